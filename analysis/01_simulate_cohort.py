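"""Simulate the study cohort.

Generates a 300-sample synthetic cohort with the default calibration: true
arm-level copy numbers (30% of arms aberrant, mostly single-copy events),
true purity ~ N(58.9, 16.3) truncated to [5, 95], serial-section replicate
purity measurements (SD 5 points), biased deconvolution/pathologist purity
observers, and noisy observed segment profiles (per-3Mb-bin log2 noise
SD 0.15). Writes the on-disk bundle every later step reads.
"""

import sys
from pathlib import Path

import numpy as np

from purecna.simulate import SimulationConfig, simulate_cohort, write_bundle

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/cohort")


def main() -> None:
    cfg = SimulationConfig(seed=SEED, n_samples=300)
    bundle = simulate_cohort(cfg)
    paths = write_bundle(bundle, OUT)

    aberrant = np.mean([cn != 2 for p in bundle.true_cn.values() for cn in p.values()])
    truths = np.array(list(bundle.true_purity.values()))
    print(f"simulated {len(bundle.sample_ids)} samples x {len(cfg.arms)} arms (seed {SEED})")
    print(f"  aberrant arm fraction: {aberrant:.3f} (target {cfg.cna_rate})")
    print(f"  true purity: mean {truths.mean():.1f}%, SD {truths.std(ddof=1):.1f}%")
    for method, per in bundle.purity.items():
        vals = np.array([e.value for e in per.values()])
        print(f"  {method:>14}: mean {vals.mean():5.1f}%, SD {vals.std(ddof=1):4.1f}%")
    for name, path in paths.items():
        print(f"  wrote {name}: {path}")


if __name__ == "__main__":
    main()
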