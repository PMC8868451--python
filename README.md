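# meatid

A desk-scale pipeline for DNA-based meat species authentication with the
mitochondrial 16S rRNA barcode. Processed meat products (mince, patties,
biltong, sausages) are routinely adulterated with cheaper species; because a
minced product cannot be identified morphologically, authentication uses a
universal amplicon: a 186-bp fragment of the mitochondrial 16S gene amplified
with universal mammalian primers and sequenced as 2×300 bp paired-end reads.
`meatid` implements the complete bioinformatics side of that workflow —
reference panel and in-silico PCR, mixture read simulation, read QC,
classification and composition profiling, contamination/mislabelling calling,
and the survey statistics — for methods development, validation and teaching.
It is aimed at food-safety bioinformaticians and molecular diagnostics groups
who want a transparent, fully deterministic re-implementation to test
thresholds and experimental designs against.

## The quantification statistic

Reads from a sample are assigned to a reference panel (one mitochondrial
reference per species, genus being the reporting unit). For each reference
*r*, the **average fold** is the depth statistic

    avg_fold(r) = aligned_bases(r) / length(r)

and the sample's composition is the **percentage average fold** per genus *g*:

    pct(g) = 100 · Σ_{r∈g} avg_fold(r) / Σ_r avg_fold(r)

A sample is **contaminated** when its highest genus percentage is strictly
below 98%; non-dominant genera below 2% are trace contaminants (attributed to
cross-contamination or database stringency rather than substitution), and a
sample whose declared species' genus is not the dominant genus is
**mislabelled**. Contaminated-vs-uncontaminated counts (k out of n) are tested
with the chi-square proportion test without continuity correction against
p₀ = ½,

    χ² = n (k/n − p₀)² / (p₀(1 − p₀)),  df = 1,

and association across sample groups uses the Pearson chi-square with
Cramér's V = √(χ² / (n_obs · min(r−1, c−1))).

## Worked example

```python
from meatid import *
from meatid.panel import meat_panel, insilico_pcr

panel = meat_panel(seed=101)                    # 9 species, 9 genera
amps  = insilico_pcr(panel)                     # one 186-bp product each

design = MixtureDesign("demo", (("pork", 0.9), ("beef", 0.1)))
reads  = simulate_sample(panel, amps, design, 10_000, error_rate=0.0, seed=3)
clean, report = apply_qc(reads)                 # adapter/quality/length QC
result  = align_reads(clean, panel)             # best-hit paired assignment
profile = composition(compute_coverage(result.hits, panel),
                      panel.genus_map, "demo", result.unassigned_pairs)
print({g: round(p, 2) for g, p in profile.entries.items()})
call = call_sample(profile)
print(call.contaminated, call.top_genus, round(call.top_pct, 2))
```

prints

```
{'Sus': 89.96, 'Bos': 10.04}
True Sus 89.96
```

— the 90:10 pork:beef design is recovered to within multinomial sampling
noise, and the sample is correctly flagged as contaminated (top genus < 98%).

The numbered drivers under `analysis/` run the full study: `01_build_panel.py`
(panel + in-silico PCR), `02_run_validation.py` (18 pure controls + 39 mixture
replicates at 10,000 pairs each; prints `mixtures called contaminated: 39/39`
and `pure controls called contaminated: 0/18`), and `03_survey_statistics.py`
(survey proportion and contingency tests; prints
`groups 2x3: chi2=81.666 p=1.85e-18 V=0.6251 ... n_obs=209` and
`verification: 14/14 statistics matched`). Tables land in `results/`. The same
stages are available from a shell via the `meatid` CLI
(`panel`, `simulate`, `qc`, `classify`, `call`, `stats`, `run-all`,
`verify-stats`).

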