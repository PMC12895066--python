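"""Plugin-based annotation pipeline.

Annotation tools are registered with a name, an execution-environment
label, and a command template with placeholders ``{input_faa}``,
``{input_fna}``, ``{input_gff}``, ``{output_tsv}``, ``{workdir}`` (plus any
per-tool params). The runner executes registered tools sequentially per
genome: it writes the genome's protein FASTA, nucleotide FASTA and GFF3
into a work directory, renders and runs the command (optionally prefixed
with an environment-activation line such as ``conda run -n ENV``),
validates the tool's tab-separated output and imports it atomically. One
failing job never aborts the rest, and never mutates the store.

Annotation TSV contract (also used for externally produced annotations):
columns locus_tag, genome, source, key, value, note.
"""

from __future__ import annotations

import json
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

from ._tsv import read_tsv
from .errors import NotFoundError, ValidationError
from .genbank import export_tracks
from .store import Store

ANNOTATION_COLUMNS = ("locus_tag", "genome", "source", "key", "value", "note")
PLACEHOLDERS = ("input_faa", "input_fna", "input_gff", "output_tsv", "workdir")
DEFAULT_ENV_PREFIX = "conda run -n {env_name} "


@dataclass
class ToolConfig:
    """Configuration of one registered annotation tool."""
    name: str
    command_template: str
    env_name: str = ""
    params: list[tuple[str, str]] = field(default_factory=list)
    enabled: bool = True


@dataclass
class JobRecord:
    job_id: int
    tool: str
    genome_id: str
    status: str  # queued | running | done | failed
    log_path: str | None = None
    n_imported: int = 0


def register_tool(store: Store, config: ToolConfig) -> ToolConfig:
    """Persist a tool configuration; re-registration under the same name overwrites."""
    if "{output_tsv}" not in config.command_template:
        raise ValidationError(
            f"tool {config.name!r}: command_template must contain {{output_tsv}}")
    with store.conn:
        store.conn.execute(
            "INSERT OR REPLACE INTO tools (name, env_name, command_template, params, enabled) "
            "VALUES (?, ?, ?, ?, ?)",
            (config.name, config.env_name, config.command_template,
             json.dumps(config.params), int(config.enabled)))
    return config


def get_tool(store: Store, name: str) -> ToolConfig:
    row = store.conn.execute("SELECT * FROM tools WHERE name = ?", (name,)).fetchone()
    if row is None:
        raise NotFoundError(f"tool not found: {name}")
    return ToolConfig(
        name=row["name"], command_template=row["command_template"],
        env_name=row["env_name"],
        params=[tuple(p) for p in json.loads(row["params"])],
        enabled=bool(row["enabled"]))


def render_command(tool: ToolConfig, env_prefix: str | None = None, **values) -> str:
    """Render a tool command by pure placeholder substitution (no shell quoting
    of values is performed beyond substitution; annotation values never enter
    templates). ``env_prefix`` is prepended with ``{env_name}`` substituted;
    pass ``None`` to run the bare command (e.g. plain scripts in tests)."""
    mapping = {k: str(v) for k, v in values.items()}
    for key, value in tool.params:
        mapping.setdefault(key, value)
    try:
        cmd = tool.command_template.format(**mapping)
    except KeyError as exc:
        raise ValidationError(f"tool {tool.name!r}: unbound placeholder {exc}") from exc
    if env_prefix and tool.env_name:
        cmd = env_prefix.format(env_name=tool.env_name) + cmd
    return cmd


def write_job_inputs(store: Store, genome_id: str, workdir: Path) -> dict[str, Path]:
    """Export the genome's track files into a work directory and return the
    placeholder mapping (input_faa, input_fna, input_gff)."""
    paths = export_tracks(store, genome_id, workdir)
    return {"input_faa": paths["faa"], "input_fna": paths["fna"],
            "input_gff": paths["gff3"]}


# ---------------------------------------------------------------------------
# Annotation TSV validation / import


def validate_annotation_tsv(tsv, store: Store) -> list[str]:
    """Per-row diagnostics for an annotation TSV; empty list means valid."""
    try:
        rows = list(read_tsv(tsv, required_columns=ANNOTATION_COLUMNS))
    except ValidationError as exc:
        return [str(exc)]
    diagnostics = []
    for lineno, row in rows:
        if not row["key"] or not row["value"]:
            diagnostics.append(f"row {lineno}: empty key or value")
            continue
        if not store.genome_exists(row["genome"]):
            diagnostics.append(f"row {lineno}: unknown genome {row['genome']!r}")
            continue
        if store.gene_by_locus(row["genome"], row["locus_tag"]) is None:
            diagnostics.append(
                f"row {lineno}: unknown locus_tag {row['locus_tag']!r} "
                f"in genome {row['genome']!r}")
    return diagnostics


def import_annotation_tsv(store: Store, tsv, skip_bad_rows: bool = False) -> int:
    """Import an annotation TSV; returns the number of rows imported.

    Rows duplicating an existing (gene, source, key, value) annotation are
    skipped silently. Without ``skip_bad_rows`` any diagnostic aborts the
    import with nothing persisted.
    """
    diagnostics = validate_annotation_tsv(tsv, store)
    if diagnostics and not skip_bad_rows:
        raise ValidationError(
            "annotation import failed:\n" + "\n".join(diagnostics))
    n = 0
    with store.conn:
        for lineno, row in read_tsv(tsv, required_columns=ANNOTATION_COLUMNS):
            if not row["key"] or not row["value"]:
                continue
            gene = store.gene_by_locus(row["genome"], row["locus_tag"]) \
                if store.genome_exists(row["genome"]) else None
            if gene is None:
                continue
            cur = store.conn.execute(
                "INSERT OR IGNORE INTO annotations "
                "(gene_id, genome_id, source, key, value, note) VALUES (?, ?, ?, ?, ?, ?)",
                (gene["gene_id"], row["genome"], row["source"] or "external",
                 row["key"], row["value"], row["note"] or None))
            n += cur.rowcount
    return n


# ---------------------------------------------------------------------------
# Pipeline runner


def run_pipeline(store: Store, genome_ids: list[str], tools: list[str],
                 scratch_root=None, env_prefix: str | None = DEFAULT_ENV_PREFIX,
                 ) -> list[JobRecord]:
    """Run each enabled tool on each genome, sequentially, importing outputs.

    Jobs are independent: a nonzero exit, missing output file or validation
    failure marks that job failed (with a log) and leaves the store
    untouched for that (genome, tool); the remaining jobs still run.
    """
    for gid in genome_ids:
        store.require_genome(gid)
    configs = [get_tool(store, name) for name in tools]
    for cfg in configs:
        if not cfg.enabled:
            raise ValidationError(f"tool {cfg.name!r} is disabled")
    scratch_root = Path(scratch_root) if scratch_root else Path(store.path).parent / "jobs"
    scratch_root.mkdir(parents=True, exist_ok=True)
    records: list[JobRecord] = []
    for genome_id in genome_ids:
        for cfg in configs:
            with store.conn:
                cur = store.conn.execute(
                    "INSERT INTO jobs (tool, genome_id, status) VALUES (?, ?, 'running')",
                    (cfg.name, genome_id))
                job_id = cur.lastrowid
            workdir = scratch_root / f"job_{job_id:05d}_{cfg.name}_{genome_id}"
            workdir.mkdir(parents=True, exist_ok=True)
            log_path = workdir / "job.log"
            out_tsv = workdir / "annotations.tsv"
            status, n_imported, log_lines = "failed", 0, []
            try:
                inputs = write_job_inputs(store, genome_id, workdir)
                cmd = render_command(cfg, env_prefix=env_prefix,
                                     output_tsv=out_tsv, workdir=workdir, **inputs)
                log_lines.append(f"$ {cmd}")
                proc = subprocess.run(cmd, shell=True, cwd=workdir,
                                      capture_output=True, text=True)
                log_lines.append(proc.stdout)
                log_lines.append(proc.stderr)
                if proc.returncode != 0:
                    log_lines.append(f"exit status {proc.returncode}")
                elif not out_tsv.exists():
                    log_lines.append("tool produced no output TSV")
                else:
                    diagnostics = validate_annotation_tsv(out_tsv, store)
                    if diagnostics:
                        log_lines.append("output validation failed:")
                        log_lines.extend(diagnostics)
                    else:
                        n_imported = import_annotation_tsv(store, out_tsv)
                        status = "done"
            except ValidationError as exc:
                log_lines.append(str(exc))
            log_path.write_text("\n".join(filter(None, log_lines)) + "\n",
                                encoding="utf-8")
            with store.conn:
                store.conn.execute(
                    "UPDATE jobs SET status = ?, log_path = ?, n_imported = ? "
                    "WHERE job_id = ?", (status, str(log_path), n_imported, job_id))
            records.append(JobRecord(job_id=job_id, tool=cfg.name, genome_id=genome_id,
                                     status=status, log_path=str(log_path),
                                     n_imported=n_imported))
    return records
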