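"""Synthetic genealogies, mutation data and geo-referenced study cohorts.

Everything downstream of sequencing is testable against these generators:
ultrametric genealogies (star or Kingman coalescent rescaled to a fixed
TMRCA), Poisson mutations dropped on an annotated circular reference at a
per-site yearly rate (mtDNA-like 20:1 transition:transversion odds), and
whole study cohorts — populations with coordinates, clade composition
gradients, a configurable fraction of control-region-only samples — with
the generating truth (clade labels, ages, frequencies) retained.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mito_io import (
    Gene,
    ReferenceSystem,
    SampleRecord,
    Variant,
    format_intervals,
    make_substitution,
    write_fasta,
    write_metadata,
    write_motif_table,
)
from .variant_scoring import (
    HaplotypeProfile,
    apply_profile,
    score_against_reference,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {65: 71, 71: 65, 67: 84, 84: 67}  # A<->G, C<->T on byte codes


# ---------------------------------------------------------------------------
# reference


def make_reference(
    length: int = 2000,
    seed: int = 0,
    control: tuple[int, int] = (1, 400),
    gene: tuple[int, int] = (401, 1600),
    rrna_trna: tuple[int, int] = (1601, 2000),
    name: str = "synthref",
) -> ReferenceSystem:
    """A small annotated circular reference: a control region, one
    protein-coding gene (so synonymous classification is exercised),
    rRNA/tRNA filler and an 'other' remainder."""
    rng = np.random.default_rng(seed)
    seq_arr = rng.choice(_BASES, size=length)
    seq = seq_arr.tobytes().decode()
    annotation: dict[str, list[tuple[int, int]]] = {
        "control": [control],
        "rRNA_tRNA": [rrna_trna],
    }
    g = Gene("SYNGENE1", gene[0], gene[1])
    for off, part in enumerate(("codon1", "codon2", "codon3")):
        annotation.setdefault(part, []).extend(
            (p, p) for p in range(gene[0] + off, gene[1] + 1, 3)
        )
    if rrna_trna[1] < length:
        annotation["other"] = [(rrna_trna[1] + 1, length)]
    return ReferenceSystem(name, seq, annotation, [g])


# ---------------------------------------------------------------------------
# genealogies


class GenealogyNode:
    """Node of an ultrametric genealogy; ``length`` is the branch above,
    in years."""

    __slots__ = ("name", "length", "children")

    def __init__(self, name: str | None = None, length: float = 0.0) -> None:
        self.name = name
        self.length = length
        self.children: list[GenealogyNode] = []

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def tips(self) -> list["GenealogyNode"]:
        return [n for n in self.walk() if not n.children]

    def height(self) -> float:
        if not self.children:
            return 0.0
        return max(c.length + c.height() for c in self.children)

    def total_length(self) -> float:
        return sum(n.length for n in self.walk() if n is not self)


def simulate_genealogy(
    n: int, tmrca: float, model: str = "star", seed: int = 0
) -> GenealogyNode:
    """Ultrametric genealogy of ``n`` tips with root height ``tmrca``.

    ``star``: every tip attaches directly to the root.  ``kingman``: a
    standard coalescent (epoch k lasts Exp(k(k-1)/2) in coalescent units,
    random pairwise joins) rescaled so the root height equals ``tmrca``.
    """
    if n < 1:
        raise ValueError("need n >= 1 tips")
    if tmrca <= 0:
        raise ValueError("tmrca must be positive")
    rng = np.random.default_rng(seed)
    if model == "star":
        root = GenealogyNode()
        for i in range(n):
            root.children.append(GenealogyNode(f"t{i + 1}", tmrca))
        return root
    if model != "kingman":
        raise ValueError(f"unknown genealogy model {model!r}")
    if n == 1:
        root = GenealogyNode()
        root.children.append(GenealogyNode("t1", tmrca))
        return root
    nodes = [GenealogyNode(f"t{i + 1}") for i in range(n)]
    heights = {id(nd): 0.0 for nd in nodes}
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = GenealogyNode()
        a.length = t - heights[id(a)]
        b.length = t - heights[id(b)]
        parent.children = [a, b]
        heights[id(parent)] = t
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    scale = tmrca / t
    for nd in root.walk():
        nd.length *= scale
    root.length = 0.0
    return root


# ---------------------------------------------------------------------------
# mutations


def drop_mutations(
    genealogy: GenealogyNode,
    mu: float,
    ref: ReferenceSystem,
    seed: int = 0,
    ts_tv: float = 20.0,
    root_sequence: str | None = None,
) -> list[HaplotypeProfile]:
    """Drop Poisson mutations on the genealogy and score the tips.

    Per-edge event counts are Poisson(mu * L * branch_years); positions
    are uniform over 1..L without within-edge repeats (repeat hits across
    edges are allowed and exercise the tree builder's conflict handling);
    the derived allele is a transition with odds ``ts_tv`` : 1, otherwise
    one of the two transversions.  Tips are scored against ``ref``, so the
    returned profiles include any events inherited from ``root_sequence``.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    rng = np.random.default_rng(seed)
    L = ref.length
    base = root_sequence if root_sequence is not None else ref.sequence
    base_arr = np.frombuffer(base.upper().encode(), dtype=np.uint8).copy()
    valid_sites = np.flatnonzero(base_arr != ord("N"))  # 0-based

    profiles: list[HaplotypeProfile] = []

    def descend(node: GenealogyNode, seq: np.ndarray) -> None:
        if node.length > 0:
            k = rng.poisson(mu * L * node.length)
            k = min(k, len(valid_sites))
            if k:
                sites = rng.choice(valid_sites, size=k, replace=False)
                for s in sites:
                    seq[s] = _mutate_base(seq[s], rng, ts_tv)
        if not node.children:
            rec = SampleRecord(node.name or "tip", seq.tobytes().decode())
            profiles.append(score_against_reference(rec, ref))
            return
        for c in node.children:
            descend(c, seq.copy())

    descend(genealogy, base_arr.copy())
    profiles.sort(key=lambda p: _tip_order(p.sample_id))
    return profiles


def _tip_order(name: str):
    return (len(name), name)


def _mutate_base(code: int, rng: np.random.Generator, ts_tv: float) -> int:
    if rng.random() < ts_tv / (ts_tv + 1.0):
        return _TRANSITION[int(code)]
    others = [b for b in (65, 67, 71, 84) if b != code and b != _TRANSITION[int(code)]]
    return others[int(rng.integers(len(others)))]


# ---------------------------------------------------------------------------
# whole clades with truth


@dataclass
class SimulatedClade:
    genealogy: GenealogyNode
    true_tmrca: float
    mu: float
    ref: ReferenceSystem
    seed: int
    profiles: list[HaplotypeProfile]
    truth_labels: dict[str, str]


def simulate_clade(
    n: int,
    tmrca: float,
    mu: float,
    ref: ReferenceSystem,
    model: str = "star",
    seed: int = 0,
    clade_name: str = "sim",
    root_sequence: str | None = None,
) -> SimulatedClade:
    """Genealogy + mutations in one go, with tips renamed per clade."""
    gen = simulate_genealogy(n, tmrca, model, seed)
    profiles = drop_mutations(gen, mu, ref, seed=seed + 1, root_sequence=root_sequence)
    renamed = []
    labels = {}
    for p in profiles:
        sid = f"{clade_name}_{p.sample_id}"
        renamed.append(
            HaplotypeProfile(sid, p.variants, p.covered_range, p.partial)
        )
        labels[sid] = clade_name
    return SimulatedClade(gen, tmrca, mu, ref, seed, renamed, labels)


# ---------------------------------------------------------------------------
# study cohorts


@dataclass
class PopulationSpec:
    name: str
    region: str
    latitude: float
    longitude: float
    n_samples: int


@dataclass
class CladeSpec:
    """One major branch: its TMRCA and per-population composition
    (fraction of that population's cohort belonging to this clade)."""

    age_years: float
    frequencies: Mapping[str, float]
    motif_size: int = 3
    n_control_variants: int = 1


def _default_populations() -> list[PopulationSpec]:
    return [
        PopulationSpec("pop_levant", "Near East", 33.0, 36.0, 25),
        PopulationSpec("pop_anatolia", "Near East", 39.0, 33.0, 25),
        PopulationSpec("pop_iran", "Near East", 32.0, 53.0, 25),
        PopulationSpec("pop_indus", "South Asia", 27.0, 68.0, 25),
        PopulationSpec("pop_ganges", "South Asia", 25.0, 83.0, 25),
        PopulationSpec("pop_deccan", "South Asia", 17.0, 77.0, 25),
        PopulationSpec("pop_balkans", "Europe", 43.0, 21.0, 25),
        PopulationSpec("pop_italy", "Europe", 42.0, 13.0, 25),
        PopulationSpec("pop_baltic", "Europe", 57.0, 25.0, 25),
        PopulationSpec("pop_aral", "Central Asia", 43.0, 60.0, 25),
        PopulationSpec("pop_tianshan", "Central Asia", 42.0, 75.0, 25),
        PopulationSpec("pop_pamir", "Central Asia", 38.0, 72.0, 25),
    ]


_REGION_COMPOSITION = {
    # clade composition of the sampled haplogroup carriers, by region:
    # 'a' dominates the Near East / South Asia, 'b' is Europe-biased and
    # younger, 'c' is South-Asia-specific; the remainder are basal lineages
    "a": {"Near East": 0.55, "South Asia": 0.50, "Europe": 0.25, "Central Asia": 0.45},
    "b": {"Near East": 0.15, "South Asia": 0.10, "Europe": 0.60, "Central Asia": 0.20},
    "c": {"Near East": 0.02, "South Asia": 0.30, "Europe": 0.00, "Central Asia": 0.05},
}


def _default_clades(populations: Sequence[PopulationSpec]) -> dict[str, CladeSpec]:
    ages = {"a": 18000.0, "b": 10000.0, "c": 6000.0}
    out = {}
    for clade, comp in _REGION_COMPOSITION.items():
        freqs = {p.name: comp[p.region] for p in populations}
        out[clade] = CladeSpec(ages[clade], freqs)
    return out


@dataclass
class StudyConfig:
    """Ground-truth study design; the defaults emulate a continental
    haplogroup survey: four regions, an old widespread branch, a younger
    Europe-biased branch, a region-specific branch, plus basal lineages,
    with ~2/5 of samples typed for the control region only."""

    populations: list[PopulationSpec] = field(default_factory=_default_populations)
    clades: dict[str, CladeSpec] | None = None
    root_age: float = 18600.0
    root_motif_size: int = 6
    root_n_control_variants: int = 2
    partial_fraction: float = 0.38
    # per-site per-year rate kept at the whole-mtDNA scale so per-site
    # homoplasy (recurrent/back mutation) matches real mitogenomes; the
    # compressed genome then carries proportionally fewer private
    # mutations per lineage
    mu: float = 2.5e-8
    genealogy_model: str = "kingman"
    reference: ReferenceSystem | None = None
    root_name: str = "HG"

    def resolved_clades(self) -> dict[str, CladeSpec]:
        clades = self.clades if self.clades is not None else _default_clades(self.populations)
        for pop in self.populations:
            tot = sum(spec.frequencies.get(pop.name, 0.0) for spec in clades.values())
            if tot > 1.0 + 1e-9:
                raise ValueError(
                    f"clade frequencies for {pop.name} sum to {tot:.3f} > 1"
                )
        return clades


@dataclass
class StudyData:
    """Everything the pipeline consumes plus the generating truth."""

    ref: ReferenceSystem
    records: list[SampleRecord]
    metadata: pd.DataFrame
    truth_labels: pd.DataFrame  # sample_id, clade
    truth_frequencies: pd.DataFrame  # population, clade, n, carriers, frequency
    truth_ages: dict[str, float]
    motifs: dict[str, list[Variant]]
    config: StudyConfig

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference_fasta": outdir / "reference.fasta",
            "reference_bed": outdir / "reference.bed",
            "samples_fasta": outdir / "samples.fasta",
            "metadata": outdir / "metadata.tsv",
            "truth_labels": outdir / "truth_labels.tsv",
            "truth_frequencies": outdir / "truth_frequencies.tsv",
            "truth_motifs": outdir / "truth_motifs.tsv",
        }
        write_fasta(
            [SampleRecord(self.ref.name, self.ref.sequence)], paths["reference_fasta"]
        )
        self.ref.to_bed(paths["reference_bed"])
        write_fasta(self.records, paths["samples_fasta"])
        write_metadata(self.metadata, paths["metadata"])
        self.truth_labels.to_csv(paths["truth_labels"], sep="\t", index=False)
        self.truth_frequencies.to_csv(paths["truth_frequencies"], sep="\t", index=False)
        write_motif_table(self.motifs, paths["truth_motifs"])
        return paths


def _draw_motif(
    rng: np.random.Generator,
    ref: ReferenceSystem,
    size: int,
    n_control: int,
    used_positions: set[int],
) -> list[Variant]:
    """Transition variants at fresh positions, ``n_control`` of them in
    the control region (real haplogroup motifs almost always include
    hypervariable-segment positions, which is what makes control-region
    typing informative)."""
    control_pool = [
        p
        for p in range(1, ref.length + 1)
        if ref.partition(p) == "control" and p not in used_positions
    ]
    other_pool = [
        p
        for p in range(1, ref.length + 1)
        if ref.partition(p) != "control" and p not in used_positions
    ]
    chosen = list(rng.choice(control_pool, size=n_control, replace=False))
    chosen += list(rng.choice(other_pool, size=size - n_control, replace=False))
    motif = []
    for pos in sorted(int(p) for p in chosen):
        used_positions.add(pos)
        anc = ref.base(pos)
        der = chr(_TRANSITION[ord(anc)])
        motif.append(make_substitution(pos, anc, der))
    return motif


def _apply_variants(seq: str, variants: Sequence[Variant]) -> str:
    arr = bytearray(seq.encode())
    for v in variants:
        arr[v.position - 1] = ord(v.derived)
    return arr.decode()


def simulate_study(config: StudyConfig | None = None, seed: int = 0) -> StudyData:
    """Generate an end-to-end study cohort with known ground truth.

    Each sample is a haplogroup carrier: it inherits the root motif, then
    (unless basal) one clade motif, then private mutations from its
    clade's genealogy.  A ``partial_fraction`` of samples are reduced to
    control-region-only coverage (sequence masked with N outside it).
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    ref = config.reference or make_reference(seed=int(rng.integers(2**31)))
    clades = config.resolved_clades()

    used: set[int] = set()
    root_motif = _draw_motif(
        rng, ref, config.root_motif_size, config.root_n_control_variants, used
    )
    motifs: dict[str, list[Variant]] = {config.root_name: root_motif}
    for name, spec in clades.items():
        motifs[config.root_name + name] = _draw_motif(
            rng, ref, spec.motif_size, spec.n_control_variants, used
        )
    root_seq = _apply_variants(ref.sequence, root_motif)

    # clade membership per sample
    members: dict[str, list[tuple[str, PopulationSpec]]] = {c: [] for c in clades}
    members["basal"] = []
    counter = 0
    meta_rows = []
    for pop in config.populations:
        names = list(clades)
        probs = [clades[c].frequencies.get(pop.name, 0.0) for c in names]
        basal_p = 1.0 - sum(probs)
        for _ in range(pop.n_samples):
            counter += 1
            sid = f"S{counter:04d}"
            draw = rng.choice(len(names) + 1, p=probs + [basal_p])
            clade = names[draw] if draw < len(names) else "basal"
            members[clade].append((sid, pop))
            meta_rows.append(
                {
                    "sample_id": sid,
                    "population": pop.name,
                    "region": pop.region,
                    "latitude": pop.latitude,
                    "longitude": pop.longitude,
                    "clade": clade,
                }
            )

    # per-clade genealogies and private mutations
    sequences: dict[str, str] = {}
    for clade, membership in members.items():
        if not membership:
            continue
        if clade == "basal":
            # basal lineages coalesce only at the haplogroup root: a hard
            # polytomy of independent branches, i.e. a star genealogy
            tmrca, base_seq, model = config.root_age, root_seq, "star"
        else:
            tmrca = clades[clade].age_years
            base_seq = _apply_variants(root_seq, motifs[config.root_name + clade])
            model = config.genealogy_model
        sub_seed = int(rng.integers(2**31))
        gen = simulate_genealogy(len(membership), tmrca, model, sub_seed)
        profiles = drop_mutations(
            gen, config.mu, ref, seed=sub_seed + 1, root_sequence=base_seq
        )
        for (sid, _pop), prof in zip(membership, profiles):
            sequences[sid] = apply_profile(prof, ref)

    # partial samples: control-region-only coverage
    all_ids = [r["sample_id"] for r in meta_rows]
    n_partial = int(round(config.partial_fraction * len(all_ids)))
    partial_ids = set(
        rng.choice(all_ids, size=n_partial, replace=False).tolist()
    )
    control_iv = [
        (s, e)
        for s, e in _annotation_intervals(ref, "control")
    ]
    records = []
    for row in meta_rows:
        sid = row["sample_id"]
        seq = sequences[sid]
        if sid in partial_ids:
            masked = bytearray(b"N" * ref.length)
            for s, e in control_iv:
                masked[s - 1 : e] = seq[s - 1 : e].encode()
            seq = masked.decode()
            row["covered"] = format_intervals(control_iv)
        else:
            row["covered"] = format_intervals([(1, ref.length)])
        records.append(
            SampleRecord(
                sid,
                seq,
                covered_range=tuple(control_iv) if sid in partial_ids else None,
                population=row["population"],
                region=row["region"],
                latitude=row["latitude"],
                longitude=row["longitude"],
            )
        )

    meta = pd.DataFrame(meta_rows)
    truth_labels = meta[["sample_id", "clade"]].copy()
    truth_labels["clade"] = truth_labels["clade"].map(
        lambda c: config.root_name if c == "basal" else config.root_name + c
    )
    freq_rows = []
    for pop in config.populations:
        sub = meta[meta["population"] == pop.name]
        for clade in clades:
            k = int((sub["clade"] == clade).sum())
            freq_rows.append(
                {
                    "population": pop.name,
                    "clade": config.root_name + clade,
                    "n_sampled": len(sub),
                    "n_carrier": k,
                    "frequency": 100.0 * k / len(sub),
                }
            )
    metadata = meta.drop(columns=["clade"])
    truth_ages = {config.root_name: config.root_age}
    truth_ages.update(
        {config.root_name + c: spec.age_years for c, spec in clades.items()}
    )
    return StudyData(
        ref=ref,
        records=records,
        metadata=metadata,
        truth_labels=truth_labels,
        truth_frequencies=pd.DataFrame(freq_rows),
        truth_ages=truth_ages,
        motifs=motifs,
        config=config,
    )


def _annotation_intervals(ref: ReferenceSystem, label: str) -> list[tuple[int, int]]:
    out = []
    start = None
    for pos in range(1, ref.length + 2):
        is_label = pos <= ref.length and ref.partition(pos) == label
        if is_label and start is None:
            start = pos
        elif not is_label and start is not None:
            out.append((start, pos - 1))
            start = None
    return out
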