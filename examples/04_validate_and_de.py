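"""Validate modules against a disease gene set and run the paired DE stage.

A module passes when at least 25% of its genes are already disease-associated;
enrichment is a hypergeometric upper tail, BH-adjusted across modules.  DEGs
need |log2FC| > 1 and BH-adjusted p < 0.01 in the paired tumor/normal test.
"""
import warnings

from mlwalk import (GeneSet, SynthConfig, de_analysis, deg_homogeneity,
                    generate_expression, generate_multilayer, ml_lcd,
                    one_sample_prop_test, validate_modules)

warnings.filterwarnings("ignore")

cfg = SynthConfig(rng_seed=0)
expr, truth = generate_expression(cfg)
net, _ = generate_multilayer(cfg, expr)
disease = GeneSet("planted", cfg.disease_gene_set())

# grow a module inside each planted block, seeding at a plain block member
block_seeds = [sorted(truth.block_members(b))[1] for b in range(3)]
communities = [ml_lcd(net, s) for s in block_seeds]
reports = validate_modules(communities, disease, len(net.universe))
print("module validation (seed, size, involvement, FDR, passes):")
for r in reports:
    print(f"  {r.seed}  {r.n_genes:>3}  {r.involvement:.3f}  "
          f"{r.overlap_fdr:.2e}  {r.passes}")

de = de_analysis(expr)
degs = de.index[de.is_deg].tolist()
print(f"\nDEGs ({len(degs)} of {len(de)} genes): {degs}")
print(f"planted DEGs: {sorted(truth.deg_genes)}")

module = communities[0]
homo = deg_homogeneity(module.members, de["log2fc"].to_dict())
print(f"module {module.seed} homogeneity: |mean log2FC| = "
      f"{homo['abs_mean_lfc']:.3f}, sd = {homo['sd_lfc']:.3f}")

# is the DEG fraction inside the module better than a 5% reference rate?
x = len(set(degs) & module.members)
stat, p = one_sample_prop_test(x, len(module.members), 0.05)
print(f"proportions test of {x}/{len(module.members)} DEGs vs 5%: "
      f"chi2 = {stat:.3f}, p = {p:.3g}")
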