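# foodbench

Benchmarking the nutrition-related commitments and practices of food
companies, end to end on synthetic study data.

The package classifies every product of a company portfolio under three
nutrient-profile systems — **Nutri-Score** (2017 points algorithm,
classes A–E), the **WHO-Europe nutrient profile model** (permitted /
not-permitted for marketing to children, category threshold table) and
**NOVA** (processing groups 1–4) — aggregates indicator-level commitment
scores into weighted per-domain and overall percentages, computes
performance indicators (portfolio healthiness, marketing permissibility,
flyer promotions, outlet density near schools on a road network), and
tests the commitment–practice relationship with Spearman rank
correlations plus Wilcoxon engagement comparisons.

Because the real study inputs (branded-food composition databases,
market-share data, retail audits, company documents) are proprietary,
the package ships a first-class **synthetic study generator** with known
ground truth: a per-company healthiness latent drives portfolio
composition, and a `coupling` parameter in [-1, 1] sets the rank
correlation between that latent and the company's commitment scores.
`coupling = 0` reproduces the null regime (no commitment–practice
correlation); `coupling = 1` with `noise_sd = 0` makes commitment and
practice rankings coincide exactly.

## Modules

| Module | Role |
|---|---|
| `foodbench.synthetic_data` | Study generator (companies, portfolios, commitment sheets, flyers, geo scenes) with ground-truth table |
| `foodbench.nutrient_profiling` | Nutri-Score / WHO / NOVA classifiers over products or dataframes |
| `foodbench.commitment_scoring` | Domain and overall score aggregation; exact Wilcoxon signed-rank and rank-sum tests |
| `foodbench.portfolio_indicators` | Per-company summaries (median class, %A/B, %D/E, %UPF, %not-permitted, %labelled) and industry aggregates |
| `foodbench.promotion_analysis` | Flyer promotion indicators, cover vs. all placements, WHO-category shares |
| `foodbench.accessibility` | Road-network shortest-path outlet-near-school proportions |
| `foodbench.stats_linkage` | Spearman correlations (exact permutation p for n ≤ 8) and the fixed commitment–practice pairing suite |
| `foodbench.pipeline` / `foodbench.cli` | Reproducible staged pipeline with manifest, checksums and CLI |

Rule tables (WHO thresholds, NOVA markers, domain weights) are versioned
YAML configuration under `src/foodbench/data/`; the shipped values are
documented defaults, replaceable per deployment.

## CLI

```bash
foodbench run-all --config config.yaml --outdir out --seed 7
# or stage by stage:
foodbench simulate --outdir out
foodbench profile --outdir out
foodbench score --outdir out
...
foodbench report --outdir out
```

The config YAML mirrors `foodbench.synthetic_data.StudyConfig`
(all fields optional). `run-all` executes
simulate → profile → score → indicators → promotions → access →
correlate → report and writes `manifest.json` with the config hash,
rule-table versions and a SHA-256 checksum per output file. Re-running
with the same config and seed reproduces byte-identical outputs.

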