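"""Readers, writers and mtDNA variant nomenclature.

Variant labels follow the PhyloTree convention used throughout the mtDNA
literature: ``T152C`` is a transition (uppercase derived allele), ``A16318t``
a transversion (lowercase derived allele), ``T16189d`` a deletion and
``573.1C`` an insertion (ordinal after the dot).  Heteroplasmy codes are
rejected.  Coordinates are 1-based closed intervals on a circular reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PARTITIONS = ("control", "rRNA_tRNA", "codon1", "codon2", "codon3", "other")

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

# standard control-region bounds for the human mitogenome; the synthetic
# reference overrides these through its annotation
CONTROL_REGION_INTERVALS = ((16024, 16569), (1, 576))


class NomenclatureError(ValueError):
    """A variant label does not conform to the nomenclature grammar."""


def is_transition(anc: str, der: str) -> bool:
    return (anc in _PURINES and der in _PURINES) or (
        anc in _PYRIMIDINES and der in _PYRIMIDINES
    )


@dataclass(frozen=True, order=True)
class Variant:
    """One scored mutation relative to the reference.

    ``kind`` is one of ``transition``, ``transversion``, ``insertion``,
    ``deletion``.  ``insertion_index`` is the ordinal of an inserted base
    (0 for anything that is not an insertion); ``derived`` is ``-`` for a
    deletion.
    """

    position: int
    ancestral: str
    derived: str
    kind: str = field(compare=False, default="transition")
    insertion_index: int = 0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise NomenclatureError(f"position must be >= 1, got {self.position}")
        if self.kind in ("transition", "transversion"):
            if self.ancestral == self.derived:
                raise NomenclatureError(
                    f"ancestral == derived ({self.ancestral}) at {self.position}"
                )
            ti = is_transition(self.ancestral, self.derived)
            if self.kind == "transition" and not ti:
                raise NomenclatureError(
                    f"{self.ancestral}->{self.derived} is not a transition pair"
                )
            if self.kind == "transversion" and ti:
                raise NomenclatureError(
                    f"{self.ancestral}->{self.derived} is not a transversion pair"
                )
        if self.kind == "insertion" and self.insertion_index < 1:
            raise NomenclatureError("insertions need insertion_index >= 1")
        if self.kind != "insertion" and self.insertion_index != 0:
            raise NomenclatureError("insertion_index must be 0 for non-insertions")

    @property
    def site(self) -> tuple[int, int]:
        """Sortable site key (position, insertion ordinal)."""
        return (self.position, self.insertion_index)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return format_variant(self)


def make_substitution(position: int, ancestral: str, derived: str) -> Variant:
    """Build a substitution Variant, inferring transition vs transversion."""
    kind = "transition" if is_transition(ancestral, derived) else "transversion"
    return Variant(position, ancestral, derived, kind)


_LABEL_RE = re.compile(r"^([ACGT])?(\d+)(?:\.(\d+))?([ACGTacgt]|d)$")


def parse_variant_label(label: str) -> Variant:
    """Parse a PhyloTree-style variant label.

    ``T152C`` -> transition; ``A16318t`` -> transversion; ``T16189d`` ->
    deletion; ``573.1C`` -> insertion number 1 after site 573.  Raises
    :class:`NomenclatureError` for malformed or non-canonical labels
    (including uppercase labels naming a transversion pair).
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise NomenclatureError(f"malformed variant label: {label!r}")
    anc, pos_s, ins_s, der = m.groups()
    pos = int(pos_s)
    if der == "d":
        if ins_s is not None:
            raise NomenclatureError(f"deletion cannot carry an insertion index: {label!r}")
        return Variant(pos, anc or "N", "-", "deletion")
    if ins_s is not None:
        if anc is not None:
            raise NomenclatureError(f"insertion label must not name an ancestral allele: {label!r}")
        if der.islower():
            raise NomenclatureError(f"insertion alleles are written uppercase: {label!r}")
        return Variant(pos, "-", der, "insertion", insertion_index=int(ins_s))
    if anc is None:
        raise NomenclatureError(f"substitution label lacks the ancestral allele: {label!r}")
    derived = der.upper()
    if derived == anc:
        raise NomenclatureError(f"ancestral and derived alleles are equal in {label!r}")
    kind = "transversion" if der.islower() else "transition"
    # canonical grammar: case encodes the mutation class, so it must agree
    # with the base pair
    if kind == "transition" and not is_transition(anc, derived):
        raise NomenclatureError(
            f"{label!r}: uppercase derived allele but {anc}->{derived} is a transversion"
        )
    if kind == "transversion" and is_transition(anc, derived):
        raise NomenclatureError(
            f"{label!r}: lowercase derived allele but {anc}->{derived} is a transition"
        )
    return Variant(pos, anc, derived, kind)


def format_variant(v: Variant) -> str:
    """Inverse of :func:`parse_variant_label` on canonical labels."""
    if v.kind == "deletion":
        anc = "" if v.ancestral in ("N", "-") else v.ancestral
        return f"{anc}{v.position}d"
    if v.kind == "insertion":
        return f"{v.position}.{v.insertion_index}{v.derived}"
    der = v.derived.lower() if v.kind == "transversion" else v.derived
    return f"{v.ancestral}{v.position}{der}"


# ---------------------------------------------------------------------------
# reference system


@dataclass
class Gene:
    """A forward-strand protein-coding gene; frame starts at ``start``."""

    name: str
    start: int  # 1-based closed
    end: int


class ReferenceSystem:
    """A circular reference sequence with a total partition annotation.

    Every position 1..L carries exactly one label from :data:`PARTITIONS`.
    Protein-coding intervals additionally record their reading frame so
    substitutions can be classified as synonymous or not.  An ``N`` in the
    sequence (such as the spacer the human reference keeps at 3107) is
    excluded from variant scoring.
    """

    def __init__(
        self,
        name: str,
        sequence: str,
        annotation: Mapping[str, Sequence[tuple[int, int]]],
        genes: Sequence[Gene] = (),
    ) -> None:
        self.name = name
        self.sequence = sequence.upper()
        self.length = len(self.sequence)
        self._seq_arr = np.frombuffer(self.sequence.encode(), dtype=np.uint8)
        self.genes = list(genes)
        labels = np.full(self.length, -1, dtype=np.int8)
        for label, intervals in annotation.items():
            if label not in PARTITIONS:
                raise ValueError(f"unknown partition label {label!r}")
            code = PARTITIONS.index(label)
            for start, end in intervals:
                if not (1 <= start <= end <= self.length):
                    raise ValueError(
                        f"interval {start}-{end} outside 1..{self.length}"
                    )
                seg = labels[start - 1 : end]
                if (seg != -1).any():
                    raise ValueError(f"overlapping annotation at {start}-{end}")
                seg[:] = code
        if (labels == -1).any():
            missing = int(np.flatnonzero(labels == -1)[0]) + 1
            raise ValueError(f"annotation is not total (first gap at {missing})")
        self._labels = labels

    def base(self, position: int) -> str:
        return self.sequence[position - 1]

    def partition(self, position: int) -> str:
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} outside 1..{self.length}")
        return PARTITIONS[self._labels[position - 1]]

    def partition_sizes(self) -> dict[str, int]:
        return {
            label: int((self._labels == i).sum())
            for i, label in enumerate(PARTITIONS)
        }

    def gene_at(self, position: int) -> Gene | None:
        for g in self.genes:
            if g.start <= position <= g.end:
                return g
        return None

    def codon_at(self, position: int) -> tuple[str, int] | None:
        """Reference codon containing ``position`` and the 0-based offset
        of ``position`` within it, or None outside annotated genes."""
        g = self.gene_at(position)
        if g is None:
            return None
        off = (position - g.start) % 3
        start = position - off
        return self.sequence[start - 1 : start + 2], off

    @classmethod
    def from_fasta_and_bed(cls, fasta_path, bed_path) -> "ReferenceSystem":
        """Load reference sequence (FASTA) plus BED-like annotation.

        The BED file is 0-based half-open, columns chrom/start/end/label.
        A label of the form ``gene:NAME`` declares a protein-coding gene;
        its positions are expanded to codon1/2/3 by reading frame.
        """
        recs = list(SeqIO.parse(str(fasta_path), "fasta"))
        if len(recs) != 1:
            raise ValueError(f"reference FASTA must hold one record, got {len(recs)}")
        seq = str(recs[0].seq).upper()
        annotation: dict[str, list[tuple[int, int]]] = {p: [] for p in PARTITIONS}
        genes: list[Gene] = []
        with open(bed_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"BED line needs 4 columns: {line!r}")
                start0, end0, label = int(fields[1]), int(fields[2]), fields[3]
                start, end = start0 + 1, end0  # to 1-based closed
                if label.startswith("gene:"):
                    gene = Gene(label[5:], start, end)
                    genes.append(gene)
                    for off, part in enumerate(("codon1", "codon2", "codon3")):
                        positions = range(start + off, end + 1, 3)
                        annotation[part].extend((p, p) for p in positions)
                else:
                    annotation[label].append((start, end))
        annotation = {k: v for k, v in annotation.items() if v}
        return cls(recs[0].id, seq, annotation, genes)

    def to_bed(self, path) -> None:
        """Write the annotation back out (genes as ``gene:NAME`` rows)."""
        rows: list[tuple[int, int, str]] = []
        gene_positions = set()
        for g in self.genes:
            rows.append((g.start - 1, g.end, f"gene:{g.name}"))
            gene_positions.update(range(g.start, g.end + 1))
        # contiguous runs of equal labels outside genes
        run_start = None
        run_label = None
        for pos in range(1, self.length + 2):
            label = self.partition(pos) if pos <= self.length else None
            if pos in gene_positions:
                label = None
            if label != run_label:
                if run_label is not None:
                    rows.append((run_start - 1, pos - 1, run_label))
                run_start, run_label = pos, label
        rows.sort()
        with open(path, "w") as fh:
            for s, e, label in rows:
                fh.write(f"{self.name}\t{s}\t{e}\t{label}\n")


# ---------------------------------------------------------------------------
# samples


@dataclass
class SampleRecord:
    """A sequenced sample: id, (possibly partial) sequence and metadata."""

    sample_id: str
    sequence: str | None = None
    covered_range: tuple[tuple[int, int], ...] | None = None
    population: str = ""
    region: str = ""
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if self.covered_range is not None:
            ivs = sorted(self.covered_range)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping covered intervals in {self.sample_id}")
            for s, e in ivs:
                if s < 1 or e < s:
                    raise ValueError(f"bad interval {s}-{e} in {self.sample_id}")
            self.covered_range = tuple(ivs)
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise ValueError(f"latitude {self.latitude} out of range")
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise ValueError(f"longitude {self.longitude} out of range")


def read_fasta(path) -> list[SampleRecord]:
    """Read sample sequences; FASTA ids become sample ids."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sample id in FASTA: {rec.id}")
        seen.add(rec.id)
        records.append(SampleRecord(sample_id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SampleRecord], path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.sample_id, description="")
        for r in records
        if r.sequence is not None
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def format_intervals(intervals: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in intervals)


def parse_intervals(text: str) -> tuple[tuple[int, int], ...]:
    if not text or text in (".", "-"):
        return ()
    out = []
    for chunk in text.split(";"):
        s, e = chunk.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


METADATA_COLUMNS = ["sample_id", "population", "region", "latitude", "longitude", "covered"]


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV keyed by sample_id."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("metadata must carry a sample_id column")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    return df.set_index("sample_id", drop=False)


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def merge_metadata(*tables: pd.DataFrame) -> pd.DataFrame:
    """Concatenate metadata tables (e.g. newly sequenced plus literature
    records), rejecting duplicate sample ids across sources."""
    merged = pd.concat(tables, ignore_index=True)
    if merged["sample_id"].duplicated().any():
        dups = merged.loc[merged["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids across sources: {dups}")
    return merged.set_index("sample_id", drop=False)


def apply_metadata(records: list[SampleRecord], meta: pd.DataFrame) -> list[SampleRecord]:
    """Attach population/region/coordinates/coverage to FASTA records."""
    out = []
    for rec in records:
        if rec.sample_id not in meta.index:
            raise ValueError(f"sample {rec.sample_id} missing from metadata")
        row = meta.loc[rec.sample_id]
        covered = None
        if "covered" in meta.columns and isinstance(row.get("covered"), str):
            ivs = parse_intervals(row["covered"])
            covered = ivs if ivs else None
        out.append(
            replace(
                rec,
                population=str(row.get("population", "")),
                region=str(row.get("region", "")),
                latitude=None if pd.isna(row.get("latitude")) else float(row["latitude"]),
                longitude=None if pd.isna(row.get("longitude")) else float(row["longitude"]),
                covered_range=covered,
            )
        )
    return out


def read_motif_table(path) -> dict[str, list[Variant]]:
    """Clade -> defining-mutation list, from a two-column TSV
    (clade, comma- or space-separated variant labels)."""
    motifs: dict[str, list[Variant]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("clade\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"motif table line {ln}: need clade<TAB>mutations")
            clade, muts = parts[0], parts[1]
            if clade in motifs:
                raise ValueError(f"duplicate clade {clade!r} in motif table")
            labels = [t for t in re.split(r"[,\s]+", muts.strip()) if t]
            motifs[clade] = [parse_variant_label(t.rstrip("!")) for t in labels]
    return motifs


def write_motif_table(motifs: Mapping[str, Sequence[Variant]], path) -> None:
    with open(path, "w") as fh:
        fh.write("clade\tdefining_mutations\n")
        for clade, variants in motifs.items():
            fh.write(f"{clade}\t{', '.join(format_variant(v) for v in variants)}\n")


# ---------------------------------------------------------------------------
# tree / alignment exports


def write_newick(tree, path) -> None:
    """Write a haplogroup tree as newick; edge variant labels travel in
    comments so standard readers can still parse the file."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def write_nexus_partitioned(
    records: Sequence[SampleRecord], ref: ReferenceSystem, path
) -> None:
    """NEXUS alignment export with one charset per genome partition, the
    layout Bayesian phylodynamics tools consume."""
    records = list(records)
    if not records:
        raise ValueError("no records to export")
    seen: set[str] = set()
    bad = []
    for r in records:
        if r.sample_id in seen:
            raise ValueError(f"duplicate sample id: {r.sample_id}")
        seen.add(r.sample_id)
        if r.sequence is None or len(r.sequence) != ref.length:
            bad.append(r.sample_id)
    if bad:
        raise ValueError(
            f"sequence length differs from reference ({ref.length}) for: {bad}"
        )
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={len(records)} NCHAR={ref.length};",
        "FORMAT DATATYPE=DNA MISSING=N GAP=-;",
        "MATRIX",
    ]
    width = max(len(r.sample_id) for r in records) + 2
    for r in records:
        lines.append(f"{r.sample_id:<{width}}{r.sequence}")
    lines += [";", "END;", "", "BEGIN SETS;"]
    for label in PARTITIONS:
        positions = [
            str(p) for p in range(1, ref.length + 1) if ref.partition(p) == label
        ]
        if not positions:
            continue
        lines.append(f"CHARSET {label} = {_compress_positions(positions)};")
    lines += ["END;"]
    Path(path).write_text("\n".join(lines) + "\n")


def _compress_positions(positions: Sequence[str]) -> str:
    """Render sorted positions as NEXUS ranges (``1-576 16024-16569``)."""
    nums = [int(p) for p in positions]
    runs = []
    start = prev = nums[0]
    for n in nums[1:]:
        if n == prev + 1:
            prev = n
            continue
        runs.append((start, prev))
        start = prev = n
    runs.append((start, prev))
    return " ".join(f"{s}-{e}" if e > s else f"{s}" for s, e in runs)
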