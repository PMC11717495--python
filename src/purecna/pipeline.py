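"""End-to-end orchestration: simulate or load a cohort, adjust copy number
with each purity method, and write the arm-call, WGII, correlation and
concordance reports plus a machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

import purecna
from purecna.adjust import (
    DEFAULT_PURITY_FLOOR,
    ArmCallSet,
    adjust_profile,
    write_adjusted_segments,
    write_arm_call_matrix,
)
from purecna.cellularity import PurityEstimate, read_purity_table
from purecna.concordance import concordance_report, report_to_json, report_to_tsv
from purecna.genome import ArmTable, SegmentProfile, default_karyotype, read_segments
from purecna.instability import wgii
from purecna.simulate import DEFAULT_BIAS_MODELS, SimulationConfig, simulate_cohort, write_bundle
from purecna.stats import pearson_ci

logger = logging.getLogger("purecna")

__all__ = ["RunConfig", "run_full", "validate_inputs", "adjust_cohort"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (CLI flags override YAML values)."""

    mode: str = "simulate"  # simulate | full (load from disk)
    outdir: Path = Path("results/run")
    seed: int | None = None
    segments_path: Path | None = None
    purity_path: Path | None = None
    arm_table_path: Path | None = None
    reference_method: str = "softctm"
    methods: Sequence[str] | None = None  # None: every method in the purity table
    purity_floor: float = DEFAULT_PURITY_FLOOR
    wgii_level: str = "arm"  # arm | segment
    min_confidence: float = 0.0
    sim: SimulationConfig | None = None

    def arms(self) -> ArmTable:
        from purecna.genome import load_arm_table

        if self.arm_table_path is not None:
            return load_arm_table(self.arm_table_path)
        return default_karyotype()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _group_by_method(estimates: Sequence[PurityEstimate]) -> dict[str, dict[str, float]]:
    grouped: dict[str, dict[str, float]] = {}
    for e in estimates:
        grouped.setdefault(e.method, {})[e.sample_id] = e.value
    return grouped


def adjust_cohort(
    profiles: Mapping[str, SegmentProfile],
    purity_by_method: Mapping[str, Mapping[str, float]],
    arms: ArmTable,
    floor: float = DEFAULT_PURITY_FLOOR,
) -> dict[str, list[ArmCallSet]]:
    """Arm-call sets per purity method over a common set of segment profiles.

    Purity values at or below zero (possible after clamping observers to the
    reporting scale) are lifted to the adjustment floor before inversion.
    """
    runs: dict[str, list[ArmCallSet]] = {}
    for method, per_sample in purity_by_method.items():
        callsets = []
        for sample_id, profile in profiles.items():
            if sample_id not in per_sample:
                raise ValueError(f"method {method}: no purity for sample {sample_id}")
            purity = max(per_sample[sample_id], 100.0 * floor)
            _, callset = adjust_profile(profile, purity, arms, floor=floor, method=method)
            callsets.append(callset)
        runs[method] = callsets
    return runs


def run_full(config: RunConfig) -> dict:
    """Run the whole chain and write every report under ``config.outdir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arms = config.arms()
    inputs: dict[str, Path] = {}
    captured: list[str] = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if config.mode == "simulate":
            if config.sim is None:
                if config.seed is None:
                    raise ValueError("simulate mode requires a seed")
                config.sim = SimulationConfig(seed=config.seed, arms=arms)
            bundle = simulate_cohort(config.sim)
            paths = write_bundle(bundle, outdir / "simulated")
            inputs.update(paths)
            profiles = bundle.profiles
            purity_by_method = {
                m: {sid: e.value for sid, e in per.items()}
                for m, per in bundle.purity.items()
            }
        else:
            if config.segments_path is None or config.purity_path is None:
                raise ValueError("full mode requires --segments and --purity paths")
            inputs["segments"] = Path(config.segments_path)
            inputs["purity"] = Path(config.purity_path)
            profiles = read_segments(config.segments_path)
            purity_by_method = _group_by_method(read_purity_table(config.purity_path))

        if config.methods is not None:
            purity_by_method = {m: purity_by_method[m] for m in config.methods}

        logger.info("adjusting %d samples with %d purity methods",
                    len(profiles), len(purity_by_method))
        runs = adjust_cohort(profiles, purity_by_method, arms, floor=config.purity_floor)

        for method, callsets in runs.items():
            write_arm_call_matrix(callsets, arms, outdir / f"arm_calls_{method}.tsv")

        # WGII table
        wgii_rows = []
        for method, callsets in runs.items():
            for cs in callsets:
                res = wgii(cs, arms)
                wgii_rows.append((res.sample_id, method, res.wgii,
                                  res.aberrant_length, res.total_length))
        with open(outdir / "wgii.tsv", "w") as fh:
            fh.write("sample_id\tmethod\twgii\taberrant_length\ttotal_length\n")
            for row in sorted(wgii_rows):
                fh.write("\t".join(str(v) for v in row) + "\n")

        # pairwise purity correlation matrix (needs >= 4 shared samples)
        methods = sorted(purity_by_method)
        shared = sorted(set.intersection(*(set(purity_by_method[m]) for m in methods)))
        corr: dict[str, dict[str, float]] = {}
        for m1 in methods:
            corr[m1] = {}
            for m2 in methods:
                x = [purity_by_method[m1][s] for s in shared]
                y = [purity_by_method[m2][s] for s in shared]
                if m1 == m2:
                    corr[m1][m2] = 1.0
                elif len(shared) >= 4 and np.ptp(x) > 0 and np.ptp(y) > 0:
                    corr[m1][m2] = round(pearson_ci(x, y).r, 4)
                else:
                    corr[m1][m2] = float("nan")
        with open(outdir / "purity_correlations.tsv", "w") as fh:
            fh.write("method\t" + "\t".join(methods) + "\n")
            for m1 in methods:
                fh.write(m1 + "\t" + "\t".join(f"{corr[m1][m2]:.4f}" for m2 in methods) + "\n")

        # concordance vs the reference method
        if config.reference_method in runs and len(runs) >= 2:
            report = concordance_report(runs, config.reference_method)
            report_to_json(report, outdir / "concordance.json")
            report_to_tsv(report, outdir / "concordance.tsv")

        captured = [str(w.message) for w in caught]

    warning_counts: dict[str, int] = {}
    for msg in captured:
        key = msg.split(";")[0].split(":")[0]
        warning_counts[key] = warning_counts.get(key, 0) + 1

    manifest = {
        "package": "purecna",
        "version": purecna.__version__,
        "mode": config.mode,
        "seed": config.seed if config.seed is not None else (config.sim.seed if config.sim else None),
        "reference_method": config.reference_method,
        "purity_floor": config.purity_floor,
        "wgii_level": config.wgii_level,
        "n_samples": len(profiles),
        "methods": sorted(runs),
        "input_digests": {name: _sha256(p) for name, p in inputs.items()},
        "warnings": warning_counts,
        "sim_config": config.sim.to_dict() if config.sim is not None else None,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def validate_inputs(config: RunConfig) -> list[str]:
    """Report dialect violations and cross-file inconsistencies (no raising)."""
    issues: list[str] = []
    import pandas as pd

    purity_samples: set[str] = set()
    segment_samples: set[str] = set()
    if config.purity_path is not None:
        try:
            df = pd.read_csv(config.purity_path, sep="\t", dtype={"sample_id": str})
            missing = {"sample_id", "method", "value"} - set(df.columns)
            if missing:
                issues.append(f"purity table missing columns {sorted(missing)}")
            else:
                bad = df[(df["value"] < 0) | (df["value"] > 100)]
                issues.extend(
                    f"purity out of range [0,100]: sample {r.sample_id} "
                    f"method {r.method} value {r.value}"
                    for r in bad.itertuples()
                )
                purity_samples = set(df["sample_id"].astype(str))
        except Exception as exc:  # malformed file is a finding, not a crash
            issues.append(f"purity table unreadable: {exc}")
    if config.segments_path is not None:
        try:
            segment_samples = set(read_segments(config.segments_path))
        except Exception as exc:
            issues.append(f"segments file unreadable: {exc}")
    if purity_samples and segment_samples:
        issues.extend(
            f"sample {s} present in segments but not in purity table"
            for s in sorted(segment_samples - purity_samples)
        )
        issues.extend(
            f"sample {s} present in purity table but not in segments"
            for s in sorted(purity_samples - segment_samples)
        )
    return issues
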