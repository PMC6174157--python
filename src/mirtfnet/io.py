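"""Plain-text readers and writers for all pipeline artifacts.

Count matrices travel as TSV with the sample metadata embedded in leading
``#``-prefixed header rows (``pair_id``, ``condition``,
``total_clean_reads``, ``uniquely_mapped_reads``, optionally a trailing
``#unit=`` line for normalized matrices); a separate ``samples.tsv``
metadata file is accepted as an alternative.  Sequences travel as FASTA
(written with U; T accepted and mapped on read), term maps as GMT
(``term_id<TAB>term_name<TAB>gene1<TAB>...``).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .quantify import SAMPLE_COLUMNS, CountMatrix, NormalizedMatrix
from .seq import normalize_rna

_META_ROWS = SAMPLE_COLUMNS  # pair_id, condition, total_clean_reads, uniquely_mapped_reads


def write_counts(cm: CountMatrix, path, lengths_path=None) -> None:
    """Write a CountMatrix as TSV with ``#`` metadata header rows."""
    path = Path(path)
    with open(path, "w") as fh:
        for key in _META_ROWS:
            vals = "\t".join(str(v) for v in cm.samples[key])
            fh.write(f"#{key}\t{vals}\n")
        cm.counts.rename_axis("feature_id").to_csv(fh, sep="\t")
    if cm.feature_lengths is not None and lengths_path is not None:
        cm.feature_lengths.rename("length_nt").rename_axis("feature_id").to_csv(
            Path(lengths_path), sep="\t"
        )


def read_counts(path, samples_path=None, lengths_path=None) -> CountMatrix:
    """Read a count TSV; metadata from ``#`` rows or a samples.tsv file."""
    path = Path(path)
    meta: dict[str, list[str]] = {}
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, *vals = line[1:].rstrip("\n").split("\t")
                meta[key] = vals
            else:
                body.append(line)
    counts = pd.read_csv(_io.StringIO("".join(body)), sep="\t", index_col=0)
    if samples_path is not None:
        samples = pd.read_csv(Path(samples_path), sep="\t", index_col=0)
    elif meta:
        missing = [k for k in _META_ROWS if k not in meta]
        if missing:
            raise InputError(f"count file {path} lacks metadata rows: {missing}")
        samples = pd.DataFrame(
            {k: meta[k] for k in _META_ROWS}, index=list(counts.columns)
        )
        samples["total_clean_reads"] = samples["total_clean_reads"].astype(int)
        samples["uniquely_mapped_reads"] = samples["uniquely_mapped_reads"].astype(int)
    else:
        raise InputError(
            f"count file {path} has no metadata header and no samples file was given"
        )
    lengths = None
    if lengths_path is not None:
        lengths = pd.read_csv(Path(lengths_path), sep="\t", index_col=0)["length_nt"]
    return CountMatrix(counts, samples, feature_lengths=lengths)


def write_normalized(nm: NormalizedMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#unit={nm.unit}\n")
        nm.values.rename_axis("feature_id").to_csv(fh, sep="\t", float_format="%.6g")


def read_normalized(path) -> NormalizedMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#unit="):
            raise InputError(f"{path} lacks a '#unit=' header line")
        unit = first.strip().split("=", 1)[1]
        values = pd.read_csv(fh, sep="\t", index_col=0)
    return NormalizedMatrix(values, unit)


def write_fasta(records: dict[str, str], path) -> None:
    """Write id -> RNA sequence as FASTA (U alphabet)."""
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into id -> normalized RNA sequence (T mapped to U)."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = normalize_rna(str(rec.seq), name=rec.id)
    return out


def write_gmt(terms: dict, path) -> None:
    """Write term_id -> (term_name, gene ids) as a GMT-like TSV."""
    with open(path, "w") as fh:
        for term_id in sorted(terms):
            name, genes = terms[term_id]
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def read_gmt(path) -> dict:
    terms = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: GMT line needs term, name, >=1 gene")
            terms[parts[0]] = (parts[1], set(parts[2:]))
    return terms


def write_tf_list(tf_ids, path) -> None:
    pd.DataFrame({"gene_id": sorted(tf_ids)}).to_csv(path, sep="\t", index=False)


def read_tf_list(path) -> set[str]:
    return set(pd.read_csv(path, sep="\t")["gene_id"])
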