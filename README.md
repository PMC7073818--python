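# pulsekin

Isoform-resolved protein turnover analysis from pulsed-SILAC DIA proteomics,
with a transcriptomics interface for alternative-splicing (AS) isoform
groups.

## The problem

In a pulsed-SILAC experiment, cells growing at steady state are switched to
medium with heavy-isotope-labeled lysine/arginine. Pre-existing proteins
stay "light"; newly synthesized ones incorporate the heavy label. For a
precursor with light intensity L and heavy intensity H, the relative
isotopic abundance

    RIA(t) = L / (L + H)

decays exponentially from 1:

    RIA(t) = RIA0 · exp(−k_loss · t),    RIA0 = 1,

where k_loss (per hour) is the rate of loss of unlabeled protein — the sum
of true degradation and dilution by cell division, k_loss = k_deg + k_cd.
pulsekin fits k_loss per precursor by nonlinear least squares (the RIA
method), or alternatively from run-normalized light-channel intensities
alone (the NLI method), aggregates precursor → peptide → AS-group rates,
and joins them with protein abundance and transcript-level mRNA abundance
(FPKM) for correlation, enrichment, and splicing-switch analyses.

Peptides are assigned against an expression-filtered protein database
(protein-coding isoforms with FPKM > 1 in ≥ 3 samples): peptides unique to
one isoform form UQ groups; peptides shared by an identical isoform set
form SM groups represented by the most abundant ("major") transcript. This
mRNA-abundance-directed grouping is what makes the turnover analysis
isoform-resolved.

The package ships a first-class synthetic-data generator
(`pulsekin.sim`) that emulates the study design — two conditions of six
samples, labeling times 0/1/4.5/11 h, replicate injections, shared/unique
tryptic peptides, lognormal noise, missingness, and a programmable fraction
of "buffered" genes whose k_loss tracks their mRNA deviations — so every
stage is testable against known ground truth.

## Worked example

```python
from pulsekin import (sim, db_builder, peptide_mapping as pm,
                      turnover, matrix_assembly as ma, stats_correlation as sc)

cfg = sim.SimConfig(n_genes=300, buffered_fraction=0.5, seed=101)
transcripts, expression, precursors, truth = sim.simulate_dataset(cfg)

db, _ = db_builder.build_filtered_db(transcripts, expression)
assignments = pm.classify_peptides(pm.build_peptide_map(db), transcripts)
groups = pm.assemble_as_groups(assignments, expression)

estimates, excluded = turnover.fit_kloss_ria_table(precursors)
agg = turnover.aggregate_kloss(estimates, assignments, groups,
                               samples=list(truth.samples))

protein, _ = ma.assemble_protein_matrix(
    ma.peptide_intensity_from_psilac(precursors), assignments, groups)
omics = ma.join_omics(protein, agg["group"], expression, groups)

per_group = sc.per_group_correlation(omics, "mRNA_kloss").dropna(subset=["rho"])
buffered = omics.meta.loc[per_group.index, "gene_id"].isin(truth.buffered_genes)
print("groups with rho:", len(per_group))
print("median rho (buffered):", round(per_group.loc[buffered, "rho"].median(), 3))
print("median rho (unbuffered):", round(per_group.loc[~buffered, "rho"].median(), 3))
print("critical |rho| at n=12:", round(sc.critical_rho(12), 3))
```

prints

```
groups with rho: 583
median rho (buffered): 0.902
median rho (unbuffered): 0.014
critical |rho| at n=12: 0.576
```

Half the simulated genes were generated with their per-sample log2 k_loss
coupled to their mRNA deviations (slope 0.8); the pipeline recovers a
strong positive per-group mRNA–k_loss Spearman correlation for exactly that
set, while the uncoupled set centers at zero. 0.576 is the two-sided
α = 0.05 significance threshold for a Spearman coefficient over 12 samples
(t-approximation), the cut used to call strongly correlated groups.

The same analyses are scriptable from the shell:

```sh
pulsekin simulate --seed 3 --out-dir simdata
pulsekin build-db --transcripts simdata/transcripts.tsv \
    --expression simdata/expression.tsv --out-dir db
pulsekin map-peptides --db db/db.fasta --expression simdata/expression.tsv \
    --out-dir map
pulsekin fit-kloss --psilac simdata/psilac.tsv --method ria --out-dir kloss
pulsekin run --config pipeline.yaml   # all eight stages, one YAML config
```

## Layout

- `pulsekin.sim` — synthetic transcriptomes, expression matrices and
  pulsed-SILAC tables with ground truth
- `pulsekin.io_formats` — strict TSV/FASTA readers and writers
- `pulsekin.db_builder` — FPKM-filtered, sample-specific protein database
- `pulsekin.peptide_mapping` — tryptic digestion, unique/shared/multi-gene
  classification, AS-group assembly
- `pulsekin.turnover` — RIA and NLI k_loss estimation and aggregation
- `pulsekin.matrix_assembly` — joined protein/k_loss/mRNA matrices
- `pulsekin.stats_correlation` — absolute/relative/per-group Spearman
  analyses, CV quintiles, differential tests
- `pulsekin.enrichment` — rank-based 1D/2D annotation enrichment
- `pulsekin.switch_events` — major-isoform switch calling and consequences
- `pulsekin.pipeline` / `pulsekin.cli` — orchestration and the `pulsekin`
  command

See `docs/methods.md` for the models, parameter choices, and limitations.
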