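# amquant

Statistical analysis and display of quantitative root colonization by
arbuscular mycorrhiza (AM) fungi.

`amquant` ingests validated CSV tables in two scoring dialects — gridline
intersect percentages (`Total, Hyphopodia, IntrHyphae, Arbuscule, Vesicle`)
and Trouvelot per-fragment score codes (`3A3`, `5A2`, `0`, ...) — computes
the Trouvelot colonization indices (F, M, m, a, A) per biological replicate,
produces replicate-aware summary tables (mean ± SE), runs per-variable
nonparametric inference (Kruskal–Wallis omnibus with rank-based Fisher-LSD
pairwise comparisons and seven p-value adjustment methods), synthesizes plot
annotations (compact letter displays or asterisks versus the control), and
exports faceted dot/bar/box plots plus bit-exact named CSV tables.

The first sample of an input table is always treated as the control, and
sample first-appearance order drives all downstream ordering.  Rows sharing
the same (sample, replicate) labels are technical replicates: grid rows are
averaged, Trouvelot rows are pooled as root fragments of one biological
replicate.

## Library overview

```python
import amquant as aq

ds = aq.read_colonization_table("gridData.csv", "grid")     # validated read
summary = aq.summarize(ds)                                  # per replicate + per sample
aq.write_summary_tables(summary, "Exp001")                  # Exp001_per_Replicate.csv, Exp001_per_Sample.csv

cmp = aq.pairwise_tests(ds, method="fdr")                   # per-variable KW + rank-LSD
aq.write_stat_table(cmp, "Exp001")                          # Exp001_stat.csv

fig = aq.plot(ds, kind="dotplot", annot="letters", method="BH", alpha=0.01)
aq.save_figure(fig, "Exp001.pdf", width=21, height=21, units="cm", dpi=300)
```

Trouvelot scores: `aq.parse_score("3A2")`,
`aq.indices_from_codes(["3A3", "5A3", "3A3"])`,
`aq.indices_per_replicate(ds)`.  Two-way ANOVA (parametric, sequential sums
of squares, residual/Q-Q diagnostics) is available via `aq.twoway_anova` for
datasets carrying an extra `trt` factor column.  Synthetic datasets for both
dialects come from `aq.simulate_grid` / `aq.simulate_trouvelot` with
mandatory seeds.

## Command-line interface

```sh
amquant summarize table.csv --type grid --out Exp001
amquant stat table.csv --type grid --method fdr --out Exp001
amquant plot table.csv --type trouvelot --kind boxplot --annot letters \
    --width 29 --height 21 --units cm --dpi 300 --out Exp001.jpeg
amquant simulate --type grid --samples "Control:80,Treated:40" --seed 7 --out sim.csv
```

A YAML config file of flag defaults can be supplied with
`amquant --config conf.yaml <subcommand> ...`; explicit flags override it.
Validation failures exit nonzero with a one-line diagnostic on stderr.

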