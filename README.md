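# lncsyn

Inference and characterization of **signed lncRNA–miRNA synergistic
interaction networks**, with a two-lncRNA prognostic risk score.

Long non-coding RNAs (lncRNAs) and microRNAs (miRNAs) both regulate mRNAs;
when a lncRNA and a miRNA share significantly more regulated mRNAs than
chance and are significantly co-expressed, they form a *synergistic pair*
whose expression correlation sign gives the interaction direction. This
package is aimed at systems-biology analysts who have (a) sample-matched
lncRNA/miRNA/mRNA expression matrices, (b) prior regulator→mRNA pair lists
with evidence counts, (c) a clinical table, and (d) disease-related RNA
id lists — and who want a tested, scriptable version of the full analysis,
plus a synthetic-data generator with planted ground truth to validate
every stage without downloading anything.

## The method

Starting from evidence-filtered priors (≥ 3 prediction programs **and**
≥ 3 CLIP-seq supports, or experimentally validated), the network is built
in four steps on preprocessed expression (≤ 30% missingness, KNN
imputation, log2):

1. lncRNA–mRNA pairs kept at BH-adjusted Pearson *p* < 0.05 (either sign);
2. miRNA–mRNA pairs kept at *r* < −0.4 and adjusted *p* < 0.05;
3. each (lncRNA, miRNA) pair with k ≥ 1 shared targets tested by the
   upper-tail hypergeometric *P*(X ≥ k) with X ~ Hypergeom(N, K, n), kept
   at adjusted *p* < 0.01;
4. the pair's own correlation assigns the sign (± = sign of r), kept at
   raw *p* < 0.05.

Downstream: power-law degree fit, 4-cycle bipartite clustering,
degree-preserving rewiring nulls, centralities, neighbor sign-consistency,
disease-RNA enrichment and Wilcoxon centrality comparisons, top-10% hub
selection, hub subnetworks and lncRNA-rooted hierarchical views, and a
risk score

    score(sample) = Σᵢ coefᵢ · expressionᵢ(sample)

with univariate Cox (Breslow) coefficients fitted on a 70% training split
and the median training score as high/low-risk cutoff, evaluated by
Kaplan–Meier curves and the log-rank test. See `docs/methods.md` for the
full model description and numerical choices.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from lncsyn import io as lio, network as lnet, survival as lsurv
from lncsyn.datatypes import ClinicalTable
from lncsyn.simulate import generate_dataset

ds = generate_dataset(seed=1)                      # 20 planted modules, 120 tumor + 30 normal samples
mats = [lio.preprocess_expression(m) for m in (ds.expr_lnc, ds.expr_mir, ds.expr_mrna)]
expr_lnc, expr_mir, expr_mrna = lio.match_samples(*mats)
priors = lio.filter_prior_pairs(ds.priors)

net, inter = lnet.build_synergistic_network(priors, expr_lnc, expr_mir, expr_mrna)
print(net.summary())

clin = ClinicalTable(ds.clinical.tumor())
train, test = lsurv.split_train_test(clin, 0.7, seed=1)
model, fits = lsurv.build_risk_model(expr_lnc, clin, list(ds.truth.risk_lnc_ids), train)
print({lnc: round(c, 4) for lnc, c in model.terms}, "cutoff", round(model.cutoff, 3))
print("test log-rank p:", lsurv.score_and_stratify(model, expr_lnc, clin, test).logrank_p)
```

prints

```
{'n_lncRNAs': 20, 'n_miRNAs': 20, 'n_edges': 20, 'n_positive': 10, 'n_negative': 10}
{'LNC0001': 0.539, 'LNC0002': 0.8223} cutoff 10.183
test log-rank p: 0.0009508880077695997
```

All 20 planted synergistic pairs are recovered (10 positive, 10 negative,
signs correct), the Cox coefficients approximate the generating log-hazard
weights (0.5, 1.1 — the second is attenuated because univariate screening
ignores the other risk factor), and the risk score separates the held-out
test samples' survival at p < 0.001.

The same workflow is available from the shell:

```bash
lncsyn simulate --seed 1 --out-dir data/
lncsyn run-all --seed 1 --out-dir run/      # writes run/manifest.json with per-stage checksums
```

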