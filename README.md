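# gfap4c

Genes that move into spatial proximity of the astrocyte master locus
*Gfap* while NPCs (neural precursor cells) differentiate into astrocytes
can be found by combining two genome-wide readouts: a bait-centric
chromosome-conformation screen (enhanced circular chromosome conformation
capture, e4C, hybridized to a restriction-fragment tiling array) and
absolute per-cell expression profiling calibrated with external spike
mRNAs. `gfap4c` implements that screen end to end as a reusable, tested
pipeline — with a synthetic-study generator standing in for the deposited
arrays — plus the downstream 3D DNA-FISH statistics used to validate
candidate associations cell by cell.

The pipeline stages are:

1. **e4C hit calling** — per-probe log2(e4C/genomic control) ratios,
   smoothed over a 200-bp sliding window; probes ≥ 2 in both biological
   replicates are hits; adjacent hits merge into peaks
   (`gfap4c.e4c`).
2. **Gene mapping** — genes within 50 kb of a peak are bait-associated;
   peak distances are binned from the TSS/TES as in the published
   candidate table (`gfap4c.mapping`).
3. **Per-cell expression** — spike-in (Percellome-style) calibration of
   array intensities to mRNA copies per cell, then the "≥ two-fold versus
   NPCs and ≥ 1 copy" upregulation filter (`gfap4c.expression`).
4. **Candidate integration** — genes exclusively associated *and*
   exclusively upregulated in LIF-induced astrocytes, with STAT3
   position-weight-matrix scanning of each candidate promoter
   (`gfap4c.integrate`, `gfap4c.motifs`).
5. **FISH statistics** — ≤ 500 nm association calls from 3D coordinates,
   residual chi-squared analysis across conditions, Fisher's exact test
   for allele-activity contrasts, Kolmogorov–Smirnov distance
   comparisons, one-way ANOVA on nuclear diameters (`gfap4c.fish`).
6. **Synthetic data** — in-silico BglII→NlaIII double digestion, probe
   design, planted contacts and expression effects, spike dosing, and
   spherical nuclei with planted association fractions, all with retained
   truth labels (`gfap4c.synthetic`).

## Worked example

Run the default synthetic study (3 chromosomes × 10 Mb, 300 genes, 20
planted associated-and-expressed genes, two replicates per condition)
through the whole screen:

```bash
python analysis/01_simulate_study.py
python analysis/02_call_e4c_hits.py
python analysis/03_screen_candidates.py
```

which prints, for seed 1:

```
NPC: 517 reproducible hits, 344 peaks; densest chromosome: chr1 (20.1/Mb)
LIF+: 849 reproducible hits, 566 peaks; densest chromosome: chr1 (27.5/Mb)
LIF-: 524 reproducible hits, 346 peaks; densest chromosome: chr1 (20.0/Mb)
20 candidates; precision 1.000, recall 1.000 against 20 planted genes;
18 candidates carry a promoter STAT3-like motif
```

chr1 carries the bait's cis contact cluster, so it ranks first in peaks
per Mb in every condition — the pattern expected for the chromosome
encoding the bait. The 20 recovered candidates are exactly the 20 planted
genes. `analysis/04_fish_validation.py` then recovers planted FISH
association fractions (0.1 / 0.4 / 0.1 across NPC / LIF+ / LIF−) within
binomial error and flags the condition difference by residual
chi-squared, and `analysis/05_published_table_reanalysis.py` re-derives
the published 18-gene candidate table's fold changes, filter survivors
and STAT3 flag count from its printed copies-per-cell values. Each script
writes its tables under `results/`.

The same stages are available as a CLI for file-based work:

```bash
gfap4c simulate --outdir sim --seed 1
gfap4c run --indir sim --outdir out
```

See `docs/methods.md` for the model, parameter and design details, and
what the synthetic study does and does not establish about real arrays.

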