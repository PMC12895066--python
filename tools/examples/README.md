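# Annotation-tool configuration examples

genomedesk does not bundle external annotation tools. Each tool is
registered with a command template; the pipeline substitutes the
placeholders `{input_faa}` (protein FASTA), `{input_fna}` (nucleotide
FASTA), `{input_gff}` (GFF3), `{output_tsv}` (where the tool's wrapper
must write the 6-column annotation TSV: `locus_tag, genome, source, key,
value, note`) and `{workdir}`, plus any per-tool `--param KEY=VALUE`
entries. When an `--env` name is set, the command is prefixed with
`conda run -n <env>` (override or disable with `--no-env`).

Most real tools do not emit the annotation TSV directly; wrap them in a
small script that runs the tool and converts its output, then register
the wrapper. The files in this directory are templates to adapt — the
tool names, environments and flags must match your installation.

Register the mock tool used by the test suite (no external software):

```
genomedesk register-tool --db collection.sqlite --name mocktool \
    --command "python mock_tool.py {input_faa} {output_tsv}"
genomedesk annotate --db collection.sqlite --tool mocktool --no-env
```
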