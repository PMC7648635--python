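# herbpersist

Tools for asking a deceptively simple question about long-term vegetation
monitoring data: **which understorey species keep their ground, and which
traits let them do it?**

In permanent-quadrat resurvey designs (here: grids of 0.25 m² quadrats in
old-growth forest, revisited eight times over twelve years), a species'
fine-scale persistence is more than the count of years it was seen — a plant
recorded in four consecutive surveys has held its microsite in a way a plant
flickering in and out four times has not. `herbpersist` implements the
**weighted residence time** (WRT) index that formalises this, together with
the surrounding analysis chain: compositional PERMANOVA, functional vs
phylogenetic diversity, and trait attribution by conditional inference
trees, plus a synthetic multi-site study generator so the whole chain can be
exercised and tested without field data.

## The persistence index

For species *i* in quadrat *m* over *Z* ordered surveys:

```
WRT_pa  = 100 · (P_im / T_im) / Z
WRT_abu = WRT_pa · Rel.cov
```

where `P` is the number of surveys with the species present, `T` the number
of maximal runs of consecutive presences, and `Rel.cov` the species' mean
share of total quadrat cover (a proportion in [0, 1]). A species present at
every survey scores 100; a species present half the time in one unbroken
block scores 50; a maximally fragmented occupant scores 100/Z. The abundance
variant discounts persistence by how little of the quadrat the species
actually occupied.

The rest of the chain:

- **PERMANOVA** (`herbpersist.permanova`) — one-way Anderson partition of
  squared Bray–Curtis distances among quadrats, pseudo-F and R², p by label
  permutation (exhaustive when feasible, seeded Monte-Carlo otherwise), for
  both species composition and trait-abundance composition.
- **FD / PD** (`herbpersist.diversity`) — mixed-type Gower trait distances
  (quantitative range-normalised, categorical mismatch, pairwise deletion of
  missing traits), mean pairwise distance per quadrat, neighbor-joining tree
  construction from any distance matrix, patristic distances, and per-site
  Spearman correlation of FD with PD (exact permutation p at small n).
- **Conditional inference trees** (`herbpersist.citree`) — recursive binary
  partitioning of WRT by the five functional traits (seed mass, belowground
  bud bank, SLA, vegetative mobility, leaf anatomy), with rank-based
  permutation tests, Bonferroni adjustment across traits, and growth that
  stops when no test rejects.
- **Synthetic studies** (`herbpersist.simulate`) — a first-order Markov
  occupancy model per (quadrat, species) with trait effects on the log-odds
  of persisting, log-normal cover, low between-site species overlap, and a
  random stand-in phylogeny.

## Worked example

The `analysis/` scripts run the full study on synthetic data. After
`python analysis/01_simulate_study.py` (4 sites × 100 quadrats × 8 surveys,
a bud-bank persistence advantage planted in the two southern sites only),
`python analysis/02_persistence_tables.py` prints:

```
  site  n_obs  mean_wrt_pa  mean_wrt_abu  pct_fully_persistent
site01   1067        35.20          8.65                  4.12
site02   1074        34.68          8.73                  3.72
site03   1122        37.43          8.51                 11.32
site04   1076        37.58          8.80                  9.85
```

— one row per site, n_obs = (species, quadrat) pairs with at least one
occurrence; the southern sites (site03/site04) show the higher persistence
their planted bud-bank effect produces. `03_composition_permanova.py`
confirms the sites differ compositionally (species composition R² = 0.10,
p = 0.001, df = 3 — low overlap spreads variance over 400 quadrats), and
`05_trait_persistence_trees.py` recovers the planted contrast:

```
--- site03 / wrt_pa (root: bud_bank) ---
split on bud_bank (p = 0.005, n = 1122)
  [bud_bank <= 0.0] leaf: n = 589, median = 12.5 [12.5, 25.0]
  [bud_bank > 0.0] leaf: n = 533, median = 50.0 [25.0, 87.5]
```

while the northern sites' trees remain single leaves (no trait passes the
permutation test). A `herbpersist` command-line interface exposes the same
stages (`herbpersist wrt|permanova|diversity|citree|simulate|run`).

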