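"""Shared fixtures: synthetic collections, hand-built GenBank files, mock tools."""

from __future__ import annotations

import shutil
from pathlib import Path

import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from genomedesk import (
    assign_orthologs, import_genbank_file, load_reference, open_store,
    predict_operons,
)
from genomedesk.store import load_taxonomy
from genomedesk.synth import CollectionSpec, synth_collection

MINI_TAXONOMY = Path(__file__).parent.parent / "src/genomedesk/data/mini_taxonomy.tsv"
MINI_REFERENCE = Path(__file__).parent.parent / "src/genomedesk/data/mini_reference.tsv"


def write_genbank(path, contig_id, sequence, features, organism=None, taxon_id=None):
    """Hand-build a small GenBank file.

    ``features``: list of (start0, end0, strand, qualifiers dict) CDS tuples
    in internal 0-based half-open coordinates.
    """
    rec = SeqRecord(Seq(sequence), id=contig_id, name=contig_id[:16],
                    description="hand-built test contig")
    rec.annotations.update(molecule_type="DNA", topology="linear",
                           data_file_division="BCT", date="01-JAN-1980")
    if organism:
        rec.annotations["organism"] = organism
        rec.annotations["source"] = organism
    quals = {}
    if organism:
        quals["organism"] = [organism]
    if taxon_id:
        quals["db_xref"] = [f"taxon:{taxon_id}"]
    rec.features.append(SeqFeature(SimpleLocation(0, len(sequence), strand=1),
                                   type="source", qualifiers=quals))
    for start, end, strand, q in features:
        rec.features.append(SeqFeature(SimpleLocation(start, end, strand=strand),
                                       type="CDS", qualifiers=q))
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write([rec], fh, "genbank")
    return Path(path)


def load_collection(collection_dir, db_path, manifest):
    """Build a fully loaded store (taxonomy, genomes, orthologs, operons)."""
    store = open_store(db_path, create=True)
    load_taxonomy(store, Path(collection_dir) / manifest["taxonomy"])
    for gid in manifest["genomes"]:
        import_genbank_file(store, Path(collection_dir) / f"{gid}.gbk")
    ref = load_reference(Path(collection_dir) / manifest["reference"])
    for gid in manifest["genomes"]:
        assign_orthologs(store, ref, gid)
    for gid in manifest["genomes"]:
        predict_operons(store, gid)
    return store


def read_truth_gene_og(collection_dir, manifest):
    rows = []
    path = Path(collection_dir) / manifest["truth_gene_og"]
    lines = path.read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        rows.append(dict(zip(header, line.split("\t"))))
    return rows


def read_truth_operons(collection_dir, manifest):
    rows = []
    path = Path(collection_dir) / manifest["truth_operons"]
    lines = path.read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        genome, contig, idx, tags = line.split("\t")
        rows.append((genome, contig, int(idx), tags.split(",")))
    return rows


# --- five-genome fixture with a planted conserved 4-gene neighborhood -------

FIVE_SPEC = CollectionSpec(n_genomes=5, genes_per_genome=40, og_pool_size=300,
                           shared_og_fraction=0.5, mutation_rate=0.05, seed=11)


@pytest.fixture(scope="session")
def five_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("five_collection")
    manifest = synth_collection(FIVE_SPEC, out)
    return out, manifest


@pytest.fixture(scope="session")
def five_store(five_dir, tmp_path_factory):
    out, manifest = five_dir
    db = tmp_path_factory.mktemp("five_db") / "collection.sqlite"
    store = load_collection(out, db, manifest)
    yield store, manifest, out
    store.close()


@pytest.fixture
def five_store_copy(five_store, tmp_path):
    """A private writable copy of the five-genome store for mutating tests."""
    store, manifest, out = five_store
    db = tmp_path / "copy.sqlite"
    shutil.copy(store.path, db)
    copy = open_store(db)
    yield copy, manifest, out
    copy.close()


@pytest.fixture
def empty_store(tmp_path):
    store = open_store(tmp_path / "empty.sqlite", create=True)
    yield store
    store.close()


# --- mock annotation tool ----------------------------------------------------

MOCK_TOOL_SCRIPT = r'''#!/usr/bin/env python3
"""Synthetic mock annotation tool: one annotation per input protein."""
import sys

faa, out_tsv = sys.argv[1], sys.argv[2]
fail_for = sys.argv[3] if len(sys.argv) > 3 else ""
headers = [l[1:].strip() for l in open(faa) if l.startswith(">")]
if fail_for and headers and headers[0].split("|")[0] == fail_for:
    sys.exit(1)
with open(out_tsv, "w") as fh:
    fh.write("locus_tag\tgenome\tsource\tkey\tvalue\tnote\n")
    for h in headers:
        genome, locus, _ = h.split("|")
        fh.write(f"{locus}\t{genome}\tmocktool\tdomain\tMOCK_{locus}\t\n")
'''


@pytest.fixture
def mock_tool_script(tmp_path):
    path = tmp_path / "mock_tool.py"
    path.write_text(MOCK_TOOL_SCRIPT, encoding="utf-8")
    return path
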