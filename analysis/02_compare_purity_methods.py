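"""Compare tumour purity estimates across methods.

Reads the simulated cohort bundle, then reports per-method marginals, the
serial-section (H&E1 vs H&E2) reproducibility correlation, the pairwise
Pearson correlation matrix, and paired t-test / Bland–Altman agreement of
each method against the cell-count reference. Writes
results/purity_comparison.tsv.
"""

from pathlib import Path

import numpy as np

from purecna.cellularity import paired_slide_concordance, read_purity_table
from purecna.stats import bland_altman, paired_ttest, pearson_ci

COHORT = Path("results/cohort")
OUT = Path("results/purity_comparison.tsv")


def main() -> None:
    estimates = read_purity_table(COHORT / "purity.tsv")
    by_method: dict[str, dict[str, float]] = {}
    for e in estimates:
        by_method.setdefault(e.method, {})[e.sample_id] = e.value
    samples = sorted(next(iter(by_method.values())))

    print("per-method marginals:")
    for method, per in sorted(by_method.items()):
        vals = np.array([per[s] for s in samples])
        print(f"  {method:>14}: mean {vals.mean():5.1f}%, SD {vals.std(ddof=1):4.1f}%")

    rep = paired_slide_concordance(by_method["softctm"], by_method["softctm_he2"])
    print(f"\nserial-section reproducibility (H&E1 vs H&E2): "
          f"r = {rep.r:.3f}, CI = ({rep.ci_low:.3f}, {rep.ci_high:.3f}), n = {rep.n}")

    methods = sorted(by_method)
    rows = []
    print("\npairwise Pearson r:")
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1:]:
            x = [by_method[m1][s] for s in samples]
            y = [by_method[m2][s] for s in samples]
            res = pearson_ci(x, y)
            rows.append((m1, m2, res.r, res.ci_low, res.ci_high))
            print(f"  {m1} vs {m2}: r = {res.r:.3f}")

    print("\nagreement with the cell-count reference (softctm, a minus b):")
    ref = [by_method["softctm"][s] for s in samples]
    agree_rows = []
    for m in methods:
        if m in ("softctm", "truth"):
            continue
        other = [by_method[m][s] for s in samples]
        t, p, md = paired_ttest(ref, other)
        ba = bland_altman(ref, other)
        agree_rows.append((m, md, ba.loa_low, ba.loa_high, p))
        print(f"  softctm - {m}: bias {md:+6.1f} points, "
              f"LoA ({ba.loa_low:+.1f}, {ba.loa_high:+.1f}), t-test p = {p:.2e}")

    OUT.parent.mkdir(parents=True, exist_ok=True)
    with open(OUT, "w") as fh:
        fh.write("comparison\tstatistic\tvalue\n")
        fh.write(f"softctm_vs_softctm_he2\tpearson_r\t{rep.r:.4f}\n")
        for m1, m2, r, lo, hi in rows:
            fh.write(f"{m1}_vs_{m2}\tpearson_r\t{r:.4f}\n")
        for m, md, lo, hi, p in agree_rows:
            fh.write(f"softctm_vs_{m}\tbias\t{md:.4f}\n")
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
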