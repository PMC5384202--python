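"""Score sample sequences against the reference and classify variants.

Sequences are assumed pre-aligned to reference coordinates (the community
convention for human mtDNA, where positions are named, not realigned); an
``N`` on either side masks the site, any other ambiguity code is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .mito_io import (
    ReferenceSystem,
    SampleRecord,
    Variant,
    format_intervals,
    format_variant,
    make_substitution,
    parse_intervals,
    parse_variant_label,
)

_VALID = frozenset("ACGTN-")

# vertebrate mitochondrial genetic code
_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]


@dataclass(frozen=True)
class HaplotypeProfile:
    """A sample's variant set relative to the reference."""

    sample_id: str
    variants: frozenset[Variant]
    covered_range: tuple[tuple[int, int], ...]
    partial: bool = False

    def covers(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.covered_range)

    def labels(self) -> list[str]:
        return [format_variant(v) for v in sorted(self.variants)]


@dataclass(frozen=True)
class SiteClass:
    """Genomic partition of a site plus, for coding substitutions, whether
    the change is synonymous."""

    position: int
    partition: str
    synonymous: bool | None = None


def _full_range(ref: ReferenceSystem) -> tuple[tuple[int, int], ...]:
    return ((1, ref.length),)


def score_against_reference(
    record: SampleRecord, ref: ReferenceSystem
) -> HaplotypeProfile:
    """Derive the variant set of ``record`` relative to ``ref``.

    One substitution Variant per differing non-N site inside the covered
    range.  Indels must arrive pre-encoded as labels (see
    :func:`profile_from_labels`); an alignment gap character in the
    sequence is treated as a deletion at that site.
    """
    if record.sequence is None:
        raise ValueError(f"{record.sample_id}: no sequence to score")
    seq = record.sequence.upper()
    covered = record.covered_range
    if len(seq) != ref.length:
        raise ValueError(
            f"{record.sample_id}: sequence length {len(seq)} != reference "
            f"length {ref.length}; partial inputs must be padded with N and "
            "carry a covered_range"
        )
    if covered is None:
        covered = _full_range(ref)
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"{record.sample_id}: ambiguity codes other than N are rejected: "
            f"{sorted(bad)}"
        )
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mask = np.zeros(ref.length, dtype=bool)
    for s, e in covered:
        if e > ref.length:
            raise ValueError(f"{record.sample_id}: interval {s}-{e} beyond reference")
        mask[s - 1 : e] = True
    n_code = ord("N")
    diff = (arr != ref._seq_arr) & mask & (arr != n_code) & (ref._seq_arr != n_code)
    variants = []
    for idx in np.flatnonzero(diff):
        pos = int(idx) + 1
        anc, der = ref.sequence[idx], seq[idx]
        if der == "-":
            variants.append(Variant(pos, anc, "-", "deletion"))
        else:
            variants.append(make_substitution(pos, anc, der))
    partial = [tuple(iv) for iv in covered] != [(1, ref.length)]
    return HaplotypeProfile(
        sample_id=record.sample_id,
        variants=frozenset(variants),
        covered_range=tuple(tuple(iv) for iv in covered),
        partial=partial,
    )


def apply_profile(profile: HaplotypeProfile, ref: ReferenceSystem) -> str:
    """Reconstruct the sample sequence over its covered range (inverse of
    :func:`score_against_reference`; uncovered sites become N)."""
    seq = list(ref.sequence)
    covered = np.zeros(ref.length, dtype=bool)
    for s, e in profile.covered_range:
        covered[s - 1 : e] = True
    for v in profile.variants:
        if v.kind == "insertion":
            continue  # insertions live between reference coordinates
        seq[v.position - 1] = "-" if v.kind == "deletion" else v.derived
    return "".join(
        c if covered[i] else "N" for i, c in enumerate(seq)
    )


def classify_variant(v: Variant, ref: ReferenceSystem) -> SiteClass:
    """Partition of the variant's site; for coding substitutions, whether
    the amino acid is unchanged under the vertebrate mitochondrial code."""
    partition = ref.partition(v.position)  # raises outside 1..L
    synonymous: bool | None = None
    if partition in ("codon1", "codon2", "codon3") and v.kind in (
        "transition",
        "transversion",
    ):
        ctx = ref.codon_at(v.position)
        if ctx is not None:
            codon, off = ctx
            mutant = codon[:off] + v.derived + codon[off + 1 :]
            synonymous = _translate(codon) == _translate(mutant)
    return SiteClass(v.position, partition, synonymous)


def _translate(codon: str) -> str:
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return str(Seq(codon).translate(table=2))


def is_synonymous(v: Variant, ref: ReferenceSystem) -> bool:
    sc = classify_variant(v, ref)
    return bool(sc.synonymous)


def restrict_profile(
    profile: HaplotypeProfile, interval_set: Sequence[tuple[int, int]]
) -> HaplotypeProfile:
    """Restrict a profile to an interval set (e.g. the control region),
    flagging the result as partial."""
    intervals = [tuple(iv) for iv in interval_set]
    if not intervals:
        raise ValueError("empty interval set")

    def inside(pos: int) -> bool:
        return any(s <= pos <= e for s, e in intervals)

    new_cov = _intersect_intervals(profile.covered_range, intervals)
    variants = frozenset(v for v in profile.variants if inside(v.position))
    return HaplotypeProfile(
        sample_id=profile.sample_id,
        variants=variants,
        covered_range=new_cov,
        partial=True,
    )


def _intersect_intervals(a, b) -> tuple[tuple[int, int], ...]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if s <= e:
                out.append((s, e))
    return tuple(sorted(out))


# ---------------------------------------------------------------------------
# profile TSV serialization


def write_profiles(profiles: Iterable[HaplotypeProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tvariants\tcovered\tpartial\n")
        for p in profiles:
            fh.write(
                f"{p.sample_id}\t{','.join(p.labels())}\t"
                f"{format_intervals(p.covered_range)}\t{int(p.partial)}\n"
            )


def read_profiles(path) -> list[HaplotypeProfile]:
    profiles = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample_id"):
            raise ValueError("profile TSV must start with a sample_id header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            sample_id, var_s, cov_s, partial_s = line.split("\t")
            variants = frozenset(
                parse_variant_label(t) for t in var_s.split(",") if t
            )
            profiles.append(
                HaplotypeProfile(
                    sample_id=sample_id,
                    variants=variants,
                    covered_range=parse_intervals(cov_s),
                    partial=bool(int(partial_s)),
                )
            )
    return profiles
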