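# Example: antimicrobial-resistance gene detection via a wrapper script
# that converts the tool's table into the genomedesk annotation TSV.
# Adapt paths/environment names to your installation before registering:
#   genomedesk register-tool --db DB --name amrfinder --env amrfinder-env \
#       --command "python wrap_amrfinder.py {input_faa} {output_tsv} --genome-from-headers"
name: amrfinder
env_name: amrfinder-env
command_template: "python wrap_amrfinder.py {input_faa} {output_tsv} --genome-from-headers"
params:
  - [threads, "4"]
notes: >
  The wrapper runs `amrfinder -p {input_faa}` and writes one row per hit
  with key "resistance_class" and value the AMR class; the protein FASTA
  headers (genome_id|locus_tag|hash) carry everything needed to fill the
  locus_tag and genome columns.
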