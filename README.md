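# purecna

Tumour purity estimation from cell counts, and purity-adjusted chromosome-arm
copy number analysis.

## The problem

Bulk tumour DNA is a mixture of neoplastic and normal diploid cells, so every
copy number alteration (CNA) in the tumour genome is diluted in proportion to
the normal-cell fraction. Interpreting segmented copy number data therefore
requires a tumour purity estimate (TPE), and different ways of obtaining one —
visual pathologist scoring, deconvolution of RNA expression or DNA
methylation, or direct counting of tumour vs non-tumour nuclei on an
H&E-stained slide by a cell-detection model — disagree systematically.
Because the purity enters the correction as a divisor, those disagreements
propagate into the called gains and losses: an *over*-estimated purity shrinks
apparent deviations from diploid and misses real CNAs (undercalling), an
*under*-estimated purity amplifies them and manufactures CNAs (overcalling).

This package implements the full analysis chain for quantifying that effect,
aimed at molecular-pathology and cancer-genomics analysts:

1. **Cell-count purity** — tumour/background nucleus detections inside
   pathologist-annotated ROIs; purity = 100·TC/(TC+BC)
   (`purecna.cellularity`).
2. **Mixture inversion** — the observed copy number of a segment is
   `cn_obs = p·cn_tumour + 2(1−p)`; adjustment solves for `cn_tumour` given a
   purity `p`, with the identity
   `cn_adj = 2 + (p/p̂)(cn_tumour − 2)` describing what a wrong estimate `p̂`
   does to the result (`purecna.adjust`).
3. **Calls and arms** — rounded tumour copy number ≥ 3 is a gain, 2 neutral,
   ≤ 1 a loss; calls aggregate to the 39 autosomal chromosome arms by
   length-weighted plurality.
4. **WGII** — the Whole Genome Instability Index, the length fraction of the
   genome with a non-neutral call (`purecna.instability`).
5. **Concordance** — 3×3 cross-tabulation of arm calls between two purity
   methods with differing/undercalling/overcalling statistics
   (`purecna.concordance`).
6. **Synthetic cohorts** — a seeded generator producing true profiles, true
   purities, biased purity observers calibrated to published cohort
   marginals, paired serial-section replicates, noisy segment profiles and
   labelled cell point patterns (`purecna.simulate`), so the whole chain is
   testable without any data download.

## Worked example

```bash
python analysis/01_simulate_cohort.py        # 300-sample synthetic cohort
python analysis/02_compare_purity_methods.py
python analysis/03_adjust_copy_number.py
python analysis/04_wgii.py
python analysis/05_concordance.py
```

The last step prints (seed 1):

```
simulated cohort (reference: softctm):
                        cp: different 338/11700 (2.9%), under 36 (10.7%), over 302 (89.3%)
                  estimate: different 319/11700 (2.7%), under 319 (100.0%), over 0 (0.0%)
            infiniumpurify: different 128/11700 (1.1%), under 128 (100.0%), over 0 (0.0%)
               softctm_he2: different 36/11700 (0.3%), under 18 (50.0%), over 18 (50.0%)
```

Read: over 300 samples × 39 arms (11,700 calls), adjusting with the
ESTIMATE-like observer (which over-estimates purity, mean 79% vs a true mean
of 59%) changes 2.7% of arm calls relative to the cell-count reference, and
every one of those disagreements is an undercall — a real CNA flattened into
neutral. The pathologist-like observer (under-estimates, mean 35%) errs in
the opposite direction: 89% of its differing calls are overcalls. Replicate
slides of the same sample (softctm vs softctm_he2) disagree on only 0.3% of
calls — the background against which the method-driven 1–3% must be judged.
The same statistics applied to the published FOCUS/GRAMPIAN cross-tabulations
(step 05, first block) give 1.5–1.7% replicate background against 6.2–14.9%
between methods, with the identical under/over asymmetry.

The same chain is scriptable through a CLI
(`purecna full --seed 1 --out results/run`; see `purecna --help`), or as a
library:

```python
import purecna as pc

cfg = pc.SimulationConfig(seed=1, n_samples=300)
bundle = pc.simulate_cohort(cfg)
segs, calls = pc.adjust_profile(bundle.profiles["S0001"],
                                bundle.true_purity["S0001"], cfg.arms)
print(pc.wgii(calls, cfg.arms).wgii)
```

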