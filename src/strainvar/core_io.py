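"""Shared data model and readers/writers for the formats the pipeline touches.

Expression data travel as a genes x samples matrix of log2 intensities with
per-sample metadata (strain label, parental-ancestry proportions, receptor
genotype).  Promoters come from a genome FASTA plus a TSS coordinate table;
motifs from JASPAR-format count matrices; everything tabular is plain TSV.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyfaidx import Fasta

log = logging.getLogger(__name__)

PARENTAL_STRAINS = ("LE", "HW", "SD")

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SampleMeta:
    """One animal/array: strain label, parental ancestry, receptor genotype.

    ``ancestry`` maps parental strain names to proportions summing to 1; a
    cross-derived line carries 0.5/0.5 of its two parents.  ``ahr_variant``
    is 1 if the animal harbours the variant receptor allele, else 0.
    """

    sample_id: str
    strain: str
    ancestry: dict[str, float] = field(default_factory=dict)
    ahr_variant: int = 0

    def __post_init__(self) -> None:
        if self.ancestry:
            total = sum(self.ancestry.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"sample {self.sample_id!r}: ancestry proportions sum to "
                    f"{total!r}, expected 1"
                )
            if any(p < 0 or p > 1 for p in self.ancestry.values()):
                raise ValueError(
                    f"sample {self.sample_id!r}: ancestry proportion outside [0,1]"
                )
        if self.ahr_variant not in (0, 1):
            raise ValueError(
                f"sample {self.sample_id!r}: ahr_variant must be 0 or 1, "
                f"got {self.ahr_variant!r}"
            )


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 intensities plus sample metadata."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")
        ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != ids:
            raise ValueError("sample metadata order does not match matrix columns")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def strains(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.strain not in seen:
                seen.append(s.strain)
        return seen

    def strain_columns(self, strain: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.strain == strain]

    def strain_means(self) -> pd.DataFrame:
        """Per-gene mean log2 intensity of each strain (genes x strains)."""
        return pd.DataFrame(
            {st: self.values[self.strain_columns(st)].mean(axis=1) for st in self.strains}
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.samples)


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.start < 0 or self.end < 0:
            raise ValueError(f"{self.gene_id}: negative coordinates")
        if not (self.start <= self.tss <= self.end):
            log.warning("%s: TSS %d outside [%d, %d]", self.gene_id, self.tss, self.start, self.end)


@dataclass
class PWM:
    """Position count matrix over A,C,G,T (4 x L, non-negative counts)."""

    motif_id: str
    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError(f"{self.motif_id}: counts must be 4 x L with L >= 1")
        if (self.counts < 0).any():
            raise ValueError(f"{self.motif_id}: negative count")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError(f"{self.motif_id}: zero column sum")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path, meta_path) -> ExpressionMatrix:
    """Read a genes x samples log2 TSV plus a sample-metadata TSV.

    The matrix file has gene ids in the first column; the metadata file is
    keyed by ``sample_id`` with columns ``strain``, ``ahr_variant`` and one
    ``ancestry_<parent>`` column per parental strain.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique()
        raise ValueError(f"duplicate gene ids in {path}: {list(dups)[:5]}")
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        for col in values.columns:
            bad = pd.to_numeric(values[col], errors="coerce").isna() & values[col].notna()
            if bad.any():
                row = values.index[bad.argmax()]
                raise ValueError(f"non-numeric cell at gene {row!r}, sample {col!r}")
        values = values.astype(float)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    samples = []
    for sid in values.columns:
        if sid not in meta.index:
            raise ValueError(f"sample {sid!r} present in matrix but missing from metadata")
        row = meta.loc[sid]
        ancestry = {
            c.removeprefix("ancestry_"): float(row[c])
            for c in meta.columns
            if c.startswith("ancestry_") and float(row[c]) > 0
        }
        samples.append(
            SampleMeta(
                sample_id=sid,
                strain=str(row["strain"]),
                ancestry=ancestry,
                ahr_variant=int(row.get("ahr_variant", 0)),
            )
        )
    return ExpressionMatrix(values.astype(float), samples)


def write_expression_matrix(X: ExpressionMatrix, path, meta_path) -> None:
    X.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.12g")
    parents = sorted({p for s in X.samples for p in s.ancestry})
    rows = []
    for s in X.samples:
        row = {"sample_id": s.sample_id, "strain": s.strain, "ahr_variant": s.ahr_variant}
        for p in parents:
            row[f"ancestry_{p}"] = s.ancestry.get(p, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# loci / annotations / homolog tables

LOCUS_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand", "tss"]


def read_loci(path) -> list[GeneLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    missing = set(LOCUS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"loci table missing columns: {sorted(missing)}")
    return [
        GeneLocus(r.gene_id, r.chromosome, int(r.start), int(r.end), r.strand, int(r.tss))
        for r in df.itertuples()
    ]


def write_loci(loci, path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": l.gene_id,
                "chromosome": l.chromosome,
                "start": l.start,
                "end": l.end,
                "strand": l.strand,
                "tss": l.tss,
            }
            for l in loci
        ]
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    """Two-column gene_id / term_id TSV mapping genes to annotation terms."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term_id"} <= set(df.columns):
        raise ValueError("annotation table needs columns gene_id, term_id")
    return df[["gene_id", "term_id"]]


def read_homolog_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ValueError("homolog map needs columns gene_a, gene_b")
    return df[["gene_a", "gene_b"]]


# ---------------------------------------------------------------------------
# JASPAR count matrices

_BRACKET_ROW = re.compile(r"^\s*([ACGTacgt])\s*\[\s*(.*?)\s*\]\s*$")


def read_jaspar(path) -> list[PWM]:
    """Read JASPAR-style count matrices.

    Accepts both the plain dialect (``>ID NAME`` then four whitespace-separated
    count rows in A,C,G,T order) and the bracketed dialect (rows like
    ``A [ 4 19 0 ]``).
    """
    motifs: list[PWM] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        line = lines[i]
        if not line.startswith(">"):
            raise ValueError(f"expected motif header, got {line!r}")
        header = line[1:].strip().split(None, 1)
        motif_id = header[0]
        name = header[1] if len(header) > 1 else motif_id
        rows: list[list[float]] = []
        order: list[str] = []
        i += 1
        while i < len(lines) and not lines[i].startswith(">") and len(rows) < 4:
            m = _BRACKET_ROW.match(lines[i])
            if m:
                order.append(m.group(1).upper())
                fields = m.group(2).split()
            else:
                fields = lines[i].split()
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise ValueError(f"motif {motif_id}: bad count row {lines[i]!r}") from exc
            i += 1
        if len(rows) != 4:
            raise ValueError(f"motif {motif_id}: expected 4 count rows, got {len(rows)}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"motif {motif_id}: count rows have unequal lengths {sorted(lengths)}")
        counts = np.array(rows, dtype=float)
        if order:
            if sorted(order) != ["A", "C", "G", "T"]:
                raise ValueError(f"motif {motif_id}: bad row labels {order}")
            counts = counts[[order.index(b) for b in "ACGT"]]
        motifs.append(PWM(motif_id, name, counts))
    return motifs


def write_jaspar(motifs, path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id} {m.name}\n")
            for b, row in zip("ACGT", m.counts):
                fh.write(b + " [ " + " ".join(f"{int(v) if v == int(v) else v}" for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# FASTA / promoters


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_promoters(
    genome, loci, upstream: int = 1000, downstream: int = 1000
) -> dict[str, str]:
    """Extract TSS-anchored windows from a genome FASTA.

    Coordinates are 1-based inclusive; the window covers ``tss - upstream``
    through ``tss + downstream`` on the gene's strand, hence spans
    ``upstream + downstream + 1`` bases (2,001 bp for the default +/-1000
    window).  Minus-strand genes are reverse-complemented, with "upstream"
    measured in transcription direction.  Windows running off a chromosome
    end are truncated with a logged warning.

    ``genome`` may be a FASTA path (random access via pyfaidx) or an
    in-memory ``{chromosome: sequence}`` mapping.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be non-negative")
    if isinstance(genome, dict):
        get_len = lambda c: len(genome[c])
        fetch = lambda c, lo, hi: genome[c][lo - 1 : hi]  # 1-based inclusive
        contigs = set(genome)
    else:
        fa = Fasta(str(genome))
        get_len = lambda c: len(fa[c])
        fetch = lambda c, lo, hi: str(fa[c][lo - 1 : hi])
        contigs = set(fa.keys())
    out: dict[str, str] = {}
    for locus in loci:
        if locus.chromosome not in contigs:
            raise KeyError(f"{locus.gene_id}: chromosome {locus.chromosome!r} not in genome")
        if locus.strand == "+":
            lo, hi = locus.tss - upstream, locus.tss + downstream
        else:
            lo, hi = locus.tss - downstream, locus.tss + upstream
        clipped_lo, clipped_hi = max(1, lo), min(get_len(locus.chromosome), hi)
        if clipped_lo != lo or clipped_hi != hi:
            log.warning(
                "%s: promoter window truncated at chromosome end (%d..%d -> %d..%d)",
                locus.gene_id, lo, hi, clipped_lo, clipped_hi,
            )
        seq = fetch(locus.chromosome, clipped_lo, clipped_hi).upper()
        out[locus.gene_id] = reverse_complement(seq) if locus.strand == "-" else seq
    return out
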