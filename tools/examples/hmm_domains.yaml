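# Example: protein-domain annotation with an HMM scanner wrapper.
name: hmm-domains
env_name: hmmer-env
command_template: "python wrap_hmmscan.py --db {profiles} {input_faa} {output_tsv}"
params:
  - [profiles, "/data/profiles/Pfam-A.hmm"]
notes: >
  The wrapper runs the scanner with --tblout, keeps hits above the
  trusted cutoff, and emits rows with key "domain" and value the profile
  accession; note is the profile description.
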