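# mitophylo

A toolkit for mitochondrial-DNA phylogeography: the analysis chain that
turns a collection of mitogenome sequences into a dated haplogroup
phylogeny and geographic frequency surfaces.

Human mtDNA studies classify maternal lineages into haplogroups — clades
defined by shared derived mutations (their *motif*) — and use the
distribution and coalescence ages of those clades to reconstruct past
dispersals. `mitophylo` implements that workflow end to end for
population geneticists working with pre-aligned mitogenomes:

- **Variant scoring** against a reference mitogenome (RSRS- or
  rCRS-style; the reference is an input, never embedded), with
  PhyloTree-style nomenclature (`T152C` transition, `A16318t`
  transversion, `573.1C` insertion, `T16189d` deletion) and per-site
  classification into the five standard genome partitions (control
  region, rRNA+tRNA, codon positions 1–3) plus synonymous/non-synonymous
  calls under the vertebrate mitochondrial code.
- **Maximum-parsimony haplogroup trees** built as weighted greedy
  perfect phylogenies: conflict-free character matrices yield the unique
  perfect phylogeny with polytomies preserved; conflicting minority
  characters recur as repeat events; hypermutable sites can be
  down-weighted. Clade-defining motifs are extracted per named clade, and
  new — possibly control-region-only — profiles are assigned to clades by
  motif matching over their covered sites.
- **ρ-statistic coalescence dating.** For a clade with `m_e` mutations on
  edge `e` subtending `n_e` of its `n` tips,

      ρ = (1/n) Σ_e m_e n_e          σ = (1/n) √( Σ_e m_e n_e² )

  (σ is the Poisson-model standard error of Saillard et al.). Ages follow
  from `t = ρ / (μ·L)` with a pluggable clock: the whole-mtDNA rate is
  the mean of the two published rates, (1.665 + 1.708)/2 × 10⁻⁸ =
  1.6865 × 10⁻⁸ substitutions/site/year, and a monotone correction
  function (e.g. a published purifying-selection curve, loadable as a
  two-column TSV) maps raw to corrected years. Clade ages are compared
  with a normal z-test on the calibrated estimates.
- **Bayesian-skyline post-processing**: parse skyline exports
  (time/mean/median/upper/lower), rescale the time axis through the same
  correction object, leave N_e untouched.
- **Spatial statistics**: per-population haplogroup frequencies, Nei's
  gene diversity `H = n/(n−1)·(1 − Σp_i²)`, and ordinary kriging of
  frequencies onto a geographic grid (great-circle distances,
  spherical/exponential/linear variograms fitted by weighted least
  squares, weights constrained to sum to 1).
- **Synthetic data with known truth**: ultrametric genealogies (star or
  rescaled Kingman coalescent), Poisson mutations on an annotated
  circular genome, and whole geo-referenced study cohorts — so every
  stage is testable without downloads.

## Worked example

```python
import mitophylo as mp
from mitophylo.synthetic_data import make_reference, simulate_clade

# a synthetic cohort: 12 populations in 4 regions, 3 clades + basal lineages
study = mp.simulate_study(seed=11)
profiles = [mp.score_against_reference(r, study.ref) for r in study.records]
complete = [p for p in profiles if not p.partial]
tree = mp.build_mp_tree(complete, root_name="U7")
print(f"{tree.n_tips()} complete mitogenomes, {tree.total_events()} mutation events")
for m in mp.extract_motifs(tree)[:3]:
    print(f"{m.clade:5s} {', '.join(m.labels())}")

# assign a control-region-only sample
motifs = {m.clade: m.variants for m in mp.extract_motifs(tree)}
partial = next(p for p in profiles if p.partial)
clade, report = mp.assign_haplogroup(partial, motifs, tree)
print(f"{partial.sample_id} (control region only) -> {clade} "
      f"(score {report.score}, matched {len(report.matched)})")

# clock-consistent dating of a simulated clade of known age 18.6 ky
ref = make_reference(length=16569, seed=7, control=(1, 1122),
                     gene=(1123, 14001), rrna_trna=(14002, 16000))
clock = mp.complete_clock()
sim = simulate_clade(30, 18600.0, clock.mu, ref, model="star", seed=5)
star = mp.build_mp_tree(sim.profiles, name_clades=False)
age = mp.rho_to_age(mp.compute_rho(star), clock)
est = mp.compute_rho(star)
print(f"rho={est.rho:.2f}+-{est.sigma:.2f} (n={est.n}) -> "
      f"{age.years/1000:.1f} ky (95% CI {age.ci_low/1000:.1f}-{age.ci_high/1000:.1f})")
```

prints

```
186 complete mitogenomes, 53 mutation events
U7    C52T, C319T, T446C, T1343C, T1362C, C1539T
U7a   A372G, T514C, A1275G
U7a1  T122a, G1993A
S0001 (control region only) -> U7b (score 3, matched 3)
rho=5.53+-0.43 (n=30) -> 19.8 ky (95% CI 16.8-22.8)
```

The first block is the cohort's reconstructed tree: the `U7` line is the
root motif (the mutations shared by every sample), `U7a` the defining
motif of the largest branch. The partial sample is placed using only the
motif variants its control-region coverage can see. The dating block
recovers the simulated clade's true age (18.6 ky) within its 95%
confidence interval: ρ = 5.53 mutations per lineage divided by
μ·L = 1.6865 × 10⁻⁸ × 16569 per year gives 19.8 ky.

Two clades of true ages 18 ky and 10 ky (n = 30 each) separate cleanly:

```python
a = mp.rho_to_age(mp.compute_rho(mp.build_mp_tree(
    simulate_clade(30, 18000.0, clock.mu, ref, seed=101).profiles, name_clades=False)), clock)
b = mp.rho_to_age(mp.compute_rho(mp.build_mp_tree(
    simulate_clade(30, 10000.0, clock.mu, ref, seed=201).profiles, name_clades=False)), clock)
z, p = mp.compare_ages(a, b)   # z=4.21, p=2.6e-05
```

The same stages are scriptable from the shell:

```sh
mitophylo all --out run1 --seed 11        # simulate -> score -> tree -> assign -> date -> map
mitophylo skyline --skyline sky.tsv --correction corr.tsv --out run1
```

Every stage records its inputs (hashed), outputs and seed in
`run1/manifest.json`.

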