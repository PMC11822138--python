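"""Condition-grid orchestration, summaries and comparisons.

Runs the bench protocol over the condition grid (mechanics x PS level x
leak kind x synchronization mode), extracts steady-state synchrony metrics
and asynchrony indices around every leak change, summarizes them as
median [IQR], and compares conditions with exact Wilcoxon rank-sum tests
(full enumeration for the small per-condition cycle counts).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import asynchrony_classifier as ac
from . import ps_controller as psc
from . import synchrony_metrics as sm
from . import virtual_bench as vb

__all__ = [
    "ConditionSpec",
    "ConditionResult",
    "SegmentResult",
    "ComparisonResult",
    "rank_sum_exact",
    "compare_conditions",
    "analyze_record",
    "run_condition",
    "run_grid",
    "write_report",
    "paper_grid",
]

METRIC_NAMES = ("td", "tiex", "ptp_trig", "ptp300", "ptp500")


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the experimental grid."""

    mechanics: str
    ps_level: float
    leak_kind: str = "inspiro-expiratory"
    sync_mode: str = "IS0"
    seed: int | None = None


@dataclass
class SegmentResult:
    """Measurements attached to one leak change within a condition."""

    level: str  # leak level active before the change
    t_change: float
    stable: bool
    medians: dict = field(default_factory=dict)
    iqrs: dict = field(default_factory=dict)
    samples: dict = field(default_factory=dict)  # per-metric 5-cycle values
    counts_steady: ac.AsynchronyCounts | None = None
    counts_post: ac.AsynchronyCounts | None = None
    ai_steady: float | None = None
    ai_post: float | None = None


@dataclass
class ConditionResult:
    spec: ConditionSpec
    segments: list[SegmentResult] = field(default_factory=list)
    error: str | None = None


@dataclass(frozen=True)
class ComparisonResult:
    p_value: float
    median_a: float
    median_b: float
    iqr_a: tuple[float, float]
    iqr_b: tuple[float, float]
    note: str = ""


# --------------------------------------------------------------------------
# Exact rank-sum test
# --------------------------------------------------------------------------

def rank_sum_exact(a, b) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum p-value, (p, note).

    Exact by full enumeration of the C(N, n_a) group assignments (midranks,
    so ties are handled) when both groups have <= 10 values; the normal
    approximation with tie correction (scipy) is used above that.  All
    pooled values identical gives p = 1 with a tie note.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs at least 3 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return 1.0, "all pooled values identical (ties)"
    if a.size > 10 or b.size > 10:
        p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        return float(p), "normal approximation with tie correction"
    ranks = stats.rankdata(pooled)
    n, n_a = pooled.size, a.size
    w_obs = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    count = total = 0
    for idx in combinations(range(n), n_a):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= dev_obs - 1e-12:
            count += 1
    note = "exact enumeration" + (" (midranks, ties present)" if np.unique(pooled).size < n else "")
    return count / total, note


def compare_conditions(a, b) -> ComparisonResult:
    """Compare two metric samples: exact rank-sum p-value plus median [IQR]."""
    p, note = rank_sum_exact(a, b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return ComparisonResult(
        p_value=p,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        iqr_a=(float(np.percentile(a, 25)), float(np.percentile(a, 75))),
        iqr_b=(float(np.percentile(b, 25)), float(np.percentile(b, 75))),
        note=note,
    )


# --------------------------------------------------------------------------
# Per-condition analysis
# --------------------------------------------------------------------------

def analyze_record(record50: vb.WaveformRecord) -> list[SegmentResult]:
    """Steady-state metrics and asynchrony windows around every leak change.

    ``record50`` must be a 50 Hz record carrying an event log.  For each
    ``leak_change`` event (skipping the initial step at t = 0): select 5
    consecutive triggered cycles out of the preceding 14 (instability rule),
    compute their per-cycle metrics, and classify asynchronies over the
    10-driver-cycle windows before and after the change.
    """
    cycles = sm.segment_cycles(record50)
    changes = [e for e in record50.events if e.type == "leak_change" and e.t > 1e-9]
    prior_levels = {}
    current = next(
        (e.payload.get("level", "L0") for e in record50.events if e.type == "leak_change" and e.t <= 1e-9),
        "L0",
    )
    for e in changes:
        prior_levels[e.t] = current
        current = e.payload.get("level", "?")

    segments: list[SegmentResult] = []
    for e in changes:
        seg = SegmentResult(level=prior_levels[e.t], t_change=e.t, stable=False)
        try:
            selection = sm.select_steady_state(cycles, e.t)
        except ValueError:
            selection = sm.SteadyStateSelection((), False)
        seg.stable = selection.stable
        if selection.stable:
            metrics = []
            for c in selection.cycles:
                try:
                    metrics.append(sm.cycle_metrics(c, record50))
                except ValueError:
                    pass
            if len(metrics) == 5:
                for name in METRIC_NAMES:
                    vals = np.array([getattr(m, name) for m in metrics])
                    seg.samples[name] = vals.tolist()
                    seg.medians[name] = float(np.median(vals))
                    seg.iqrs[name] = (
                        float(np.percentile(vals, 25)),
                        float(np.percentile(vals, 75)),
                    )
            else:
                seg.stable = False
        for which, attr_counts, attr_ai in (
            ("steady_state", "counts_steady", "ai_steady"),
            ("post_modification", "counts_post", "ai_post"),
        ):
            win = ac.extract_window(record50, e.t, which)
            if win is not None:
                counts = ac.classify_window(*win, window=which)
                setattr(seg, attr_counts, counts)
                try:
                    setattr(seg, attr_ai, ac.asynchrony_index(counts).total)
                except ValueError:
                    pass
        segments.append(seg)
    return segments


def run_condition(
    spec: ConditionSpec,
    calibration: dict,
    protocol: vb.ProtocolSpec = vb.ProtocolSpec(),
    noise: vb.NoiseSpec | None = None,
) -> ConditionResult:
    """Simulate and analyze one grid cell.

    ``calibration`` holds the shared calibrations: ``effort`` (an
    EffortProfile calibrated on the normal-mechanics timing) and
    ``leaks[kind][level]`` LeakSpecs.
    """
    result = ConditionResult(spec=spec)
    try:
        mech = vb.mechanics_preset(spec.mechanics)
        effort = vb.effort_profile_for(spec.mechanics, calibration["effort"])
        settings = psc.settings_for(spec.mechanics, spec.ps_level)
        leak_specs = calibration["leaks"][spec.leak_kind]
        rec = vb.run_protocol(
            mech,
            effort,
            settings,
            spec.sync_mode,
            spec.leak_kind,
            leak_specs,
            protocol=protocol,
            seed=spec.seed,
            noise=noise,
        )
        result.segments = analyze_record(sm.downsample_to_50hz(rec))
    except Exception as exc:  # noqa: BLE001 - per-condition isolation
        result.error = f"{type(exc).__name__}: {exc}"
    return result


def run_grid(
    grid: list[ConditionSpec],
    calibration: dict,
    protocol: vb.ProtocolSpec = vb.ProtocolSpec(),
    noise: vb.NoiseSpec | None = None,
) -> list[ConditionResult]:
    """Run every condition independently; failures are isolated per cell."""
    return [run_condition(spec, calibration, protocol, noise) for spec in grid]


def paper_grid(seed: int = 0, modes=("IS0", "ISIE")) -> list[ConditionSpec]:
    """The 36-setup design: 3 mechanics x 2 PS x (3 leak levels within each
    record) x 2 activation modes, for each leak kind."""
    grid = []
    i = 0
    for kind in ("inspiro-expiratory", "inspiratory-only"):
        for mech in ("normal", "obstructive", "restrictive"):
            for ps in (8.0, 14.0):
                for mode in modes:
                    grid.append(ConditionSpec(mech, ps, kind, mode, seed + i))
                    i += 1
    return grid


# --------------------------------------------------------------------------
# Reporting
# --------------------------------------------------------------------------

def _results_frame(results: list[ConditionResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        base = dict(
            mechanics=res.spec.mechanics,
            ps_level=res.spec.ps_level,
            leak_kind=res.spec.leak_kind,
            sync_mode=res.spec.sync_mode,
            seed=res.spec.seed,
            error=res.error or "",
        )
        if not res.segments:
            rows.append(base)
            continue
        for k, seg in enumerate(res.segments):
            row = dict(base)
            row.update(
                segment=k,
                level=seg.level,
                t_change=seg.t_change,
                stable=seg.stable,
                ai_steady=seg.ai_steady,
                ai_post=seg.ai_post,
            )
            for name in METRIC_NAMES:
                row[f"{name}_median"] = seg.medians.get(name)
                iqr = seg.iqrs.get(name)
                row[f"{name}_q1"] = iqr[0] if iqr else None
                row[f"{name}_q3"] = iqr[1] if iqr else None
            if seg.counts_post is not None:
                row["auto_triggering_post"] = seg.counts_post.auto_triggering
                row["late_cycling_post"] = seg.counts_post.late_cycling
            rows.append(row)
    return pd.DataFrame(rows)


def _comparison_frame(results: list[ConditionResult]) -> pd.DataFrame:
    """The three comparison families: IS0 vs ISIE (Td and Tiex), ISI vs ISIE
    on Td, ISE vs ISIE on Tiex, per setting and leak level."""
    by_key: dict[tuple, dict[str, dict[str, list[float]]]] = {}
    for res in results:
        for seg in res.segments:
            if not seg.stable:
                continue
            key = (res.spec.mechanics, res.spec.ps_level, res.spec.leak_kind, seg.level)
            by_key.setdefault(key, {}).setdefault(res.spec.sync_mode, {})
            for name in METRIC_NAMES:
                by_key[key][res.spec.sync_mode].setdefault(name, []).extend(
                    seg.samples.get(name, [])
                )
    families = [
        ("IS0", "ISIE", METRIC_NAMES),
        ("ISI", "ISIE", ("td",)),
        ("ISE", "ISIE", ("tiex",)),
    ]
    rows = []
    for key, modes in sorted(by_key.items()):
        for mode_a, mode_b, metrics in families:
            if mode_a not in modes or mode_b not in modes:
                continue
            for name in metrics:
                a = modes[mode_a].get(name, [])
                b = modes[mode_b].get(name, [])
                if len(a) < 3 or len(b) < 3:
                    continue
                cmp_res = compare_conditions(a, b)
                rows.append(
                    dict(
                        mechanics=key[0],
                        ps_level=key[1],
                        leak_kind=key[2],
                        level=key[3],
                        comparison=f"{mode_a}_vs_{mode_b}",
                        metric=name,
                        p_value=cmp_res.p_value,
                        median_a=cmp_res.median_a,
                        median_b=cmp_res.median_b,
                        note=cmp_res.note,
                    )
                )
    return pd.DataFrame(rows)


def write_report(
    results: list[ConditionResult],
    outdir: "str | Path",
    config: dict | None = None,
    make_plots: bool = True,
) -> dict:
    """Write per-condition metrics CSV, comparison table, summary plots and
    a JSON manifest; returns the manifest dict.  Deterministic for a given
    result set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = _results_frame(results)
    comp = _comparison_frame(results)
    df.to_csv(outdir / "condition_metrics.csv", index=False, float_format="%.6g")
    comp.to_csv(outdir / "comparisons.csv", index=False, float_format="%.6g")

    if make_plots and not df.empty and "td_median" in df:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for metric in ("td", "tiex"):
            col = f"{metric}_median"
            sub = df.dropna(subset=[col]) if col in df else pd.DataFrame()
            if sub.empty:
                continue
            fig, ax = plt.subplots(figsize=(7, 4))
            groups = sub.groupby("sync_mode")[col]
            ax.boxplot(
                [vals.values for _, vals in groups], tick_labels=list(groups.groups)
            )
            ax.set_ylabel(f"{metric} (s)")
            ax.set_title(f"{metric} medians across conditions by activation mode")
            fig.tight_layout()
            fig.savefig(outdir / f"{metric}_summary.png", dpi=110)
            plt.close(fig)

    config = config or {}
    cfg_text = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "n_conditions": len(results),
        "n_errors": sum(1 for r in results if r.error),
        "seeds": [r.spec.seed for r in results],
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
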