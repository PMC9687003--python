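"""Classify PSB / -1 / +1 interfaces and compare their co-alignment curves.

Reproduces the live-imaging analysis on synthetic data: with high boundary
tension (beta = 0.9, wild-type-like) the PSB curve stays high while the
control interface columns decay; with beta = 0 (tartan-like mutant) the
three columns are indistinguishable.
"""

from psboundary import (SynthesisConfig, compare_conditions, generate_epithelium,
                        interfaces_to_table)


def curves_for(beta: float):
    cfg = SynthesisConfig(beta=beta, seed=2)
    tissue = generate_epithelium(cfg)
    en = set(tissue.cell_truth.query("en_positive").cell_id)
    tab = interfaces_to_table(tissue, {f.index: en for f in tissue.frames})
    return compare_conditions(tab, t_test=30.0)


for beta in (0.9, 0.0):
    report = curves_for(beta)
    print(f"\nbeta = {beta} "
          f"({'wild-type-like' if beta > 0 else 'tartan-like mutant'})")
    at30 = report["curves"].query("time_min == 30.0")
    for row in at30.itertuples():
        print(f"  {row.condition:>6}: proportion > 60 deg at t=30 = "
              f"{row.proportion:.2f} (LOESS fit {row.loess_fit:.2f})")
    for (a, b), r in report["ks"].items():
        print(f"  KS {a} vs {b} at 30 min: D = {r.statistic:.2f}, "
              f"p = {r.pvalue:.2e} [{r.stars}]")
# A significant PSB-vs-control difference (***) appears only when boundary
# tension is present; at beta = 0 the tests are non-significant (ns).
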