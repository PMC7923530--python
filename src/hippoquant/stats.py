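"""Group-comparison statistics and the three-condition study harness.

Implements the study's statistical toolkit - control-normalized percent
differences, one-way ANOVA with Bonferroni-corrected pooled-variance post
hoc t tests, Bonferroni-adjusted unpaired t tests and two-tailed variance F
tests - and a seeded end-to-end harness that generates synthetic cohorts
for the three conditions, runs all three quantification arms and assembles
the results tables.

The decompositions are written out explicitly (SSB/SSW, pooled variance)
with tail probabilities from scipy's F and t distributions; spines pooled
across dendrites and mice are treated as independent observations, as in
the source analyses (no mixed-effects modeling - a documented limitation).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult", "percent_diff_from_control", "one_way_anova_bonferroni",
    "t_test_bonferroni", "variance_f_test", "StudyConfig", "run_study",
]


@dataclass
class ComparisonResult:
    """One-way ANOVA with Bonferroni post hoc pairwise tests."""

    F_stat: float
    df: Tuple[int, int]
    p_value: float
    pairwise: Dict[Tuple[str, str], float]
    percent_diff: Dict[str, float]


def percent_diff_from_control(values, control_mean: float) -> np.ndarray:
    """Per-value percent difference from the control-group mean."""
    if control_mean == 0:
        raise ValueError("percent difference undefined for zero control mean")
    values = np.asarray(values, dtype=float)
    return 100.0 * (values - control_mean) / control_mean


def _pooled_t(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """Two-tailed pooled-variance (Student) t test: returns (t, raw p)."""
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = na + nb - 2
    pooled = ((na - 1) * va + (nb - 1) * vb) / df
    diff = a.mean() - b.mean()
    if pooled == 0:
        return (0.0, 1.0) if diff == 0 else (math.inf, 0.0)
    tstat = diff / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    return float(tstat), float(2.0 * sps.t.sf(abs(tstat), df))


def t_test_bonferroni(a, b, n_comparisons: int = 1) -> float:
    """Bonferroni-adjusted two-tailed unpaired Student t test p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    _, p = _pooled_t(a, b)
    return min(1.0, p * n_comparisons)


def variance_f_test(a, b) -> Tuple[float, float]:
    """Two-tailed F test of variance equality: F = var(a)/var(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise ValueError("zero denominator variance; F undefined")
    F = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p = 2.0 * min(sps.f.sf(F, dfa, dfb), sps.f.cdf(F, dfa, dfb))
    return float(F), float(min(p, 1.0))


def one_way_anova_bonferroni(groups: Mapping[str, Sequence[float]],
                             control: Optional[str] = None) -> ComparisonResult:
    """One-way ANOVA (SSB/SSW decomposition) with Bonferroni post hoc tests.

    ``groups`` maps condition names to per-subject values.  Pairwise p-values
    are pooled-variance t tests multiplied by the number of pairs (capped at
    1).  ``percent_diff`` holds each group mean's percent difference from the
    control mean (the first group if ``control`` is not given).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs >= 2 values")

    grand = np.concatenate(list(arrays.values()))
    grand_mean = grand.mean()
    ssb = sum(a.size * (a.mean() - grand_mean) ** 2 for a in arrays.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_between = len(names) - 1
    df_within = grand.size - len(names)
    msb = ssb / df_between
    msw = ssw / df_within
    if msw == 0:
        F = 0.0 if msb == 0 else math.inf
        p = 1.0 if msb == 0 else 0.0
    else:
        F = msb / msw
        p = float(sps.f.sf(F, df_between, df_within))

    pairs = list(itertools.combinations(names, 2))
    pairwise = {pair: t_test_bonferroni(arrays[pair[0]], arrays[pair[1]],
                                        n_comparisons=len(pairs))
                for pair in pairs}

    control = control or names[0]
    cmean = arrays[control].mean()
    pct = {k: (float(percent_diff_from_control([a.mean()], cmean)[0])
               if cmean != 0 else math.nan)
           for k, a in arrays.items()}
    return ComparisonResult(F_stat=float(F), df=(df_between, df_within),
                            p_value=p, pairwise=pairwise, percent_diff=pct)


# ---------------------------------------------------------------------------
# end-to-end study harness

@dataclass(frozen=True)
class StudyConfig:
    """Cohort sizes and analysis settings for a synthetic three-condition
    study.  Conditions map study groups onto generator presets per arm."""

    arms: Tuple[str, ...] = ("memri", "em", "ephys")
    conditions: Tuple[str, ...] = ("control", "demyelinated", "remyelinated")
    n_memri: int = 10
    n_dendrites: int = 9
    shaft_length_um: float = 12.0
    n_sweeps: int = 16
    q_level: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.q_level < 1:
            raise ValueError("q_level must lie in (0, 1)")
        unknown = set(self.arms) - {"memri", "em", "ephys"}
        if unknown:
            raise ValueError(f"unknown arms: {sorted(unknown)}")


_EM_CONDITION = {"control": "myelinated", "demyelinated": "demyelinated",
                 "remyelinated": "remyelinated"}


def subject_seed(base_seed: int, arm: str, condition: str, index: int) -> int:
    """Deterministic per-subject seed below 2**31."""
    h = (base_seed * 1_000_003 + hash((arm, condition)) % 9973 * 131
         + index * 7919) % (2 ** 31 - 1)
    return int(h)


def run_study(config: StudyConfig, seed: int,
              out_dir: Optional[Path] = None) -> Dict[str, pd.DataFrame]:
    """Generate cohorts for every condition, run all arms, assemble tables.

    Returns a dict of DataFrames (one per arm plus a comparison table);
    pure function of ``(config, seed)`` - rerunning with the same arguments
    reproduces the tables byte-identically.  MRI group comparisons run on
    control-normalized percent differences.
    """
    from hippoquant import memri as mq
    from hippoquant import presets as ps
    from hippoquant import synthetic as syn
    from hippoquant.ephys import FeatureConfig, extract_features
    from hippoquant.spines import analyze_stack

    tables: Dict[str, pd.DataFrame] = {}
    comparisons: List[dict] = []

    if "memri" in config.arms:
        rows = []
        for cond in config.conditions:
            preset = ps.get_preset("memri", cond if cond != "remyelinated"
                                   else "remyelinated")
            for i in range(config.n_memri):
                pair, _ = syn.gen_memri_pair(
                    preset, subject_seed(seed, "memri", cond, i))
                emap = mq.enhancement_test(pair, q_level=config.q_level)
                rows.append({
                    "condition": cond, "subject": i,
                    "evol_mm3": emap.evol_mm3,
                    "hippo_volume_mm3": mq.hippocampal_volume(
                        pair.hippo_mask, pair.voxel_mm),
                    "sigma_hat": emap.sigma_hat, "q_level": emap.q_level})
        df = pd.DataFrame(rows)
        tables["memri"] = df
        for metric in ("evol_mm3", "hippo_volume_mm3"):
            groups = {c: df.loc[df.condition == c, metric].to_numpy()
                      for c in config.conditions}
            cmean = groups[config.conditions[0]].mean()
            pct_groups = {c: percent_diff_from_control(v, cmean)
                          for c, v in groups.items()}
            res = one_way_anova_bonferroni(pct_groups,
                                           control=config.conditions[0])
            # the values under test are already control-normalized percent
            # differences, so report their group means directly
            res.percent_diff = {c: float(np.mean(v))
                                for c, v in pct_groups.items()}
            comparisons.append(_comparison_row("memri", metric, res))

    if "em" in config.arms:
        rows = []
        for cond in config.conditions:
            preset = ps.get_preset("em", _EM_CONDITION[cond])
            for i in range(config.n_dendrites):
                stack, _ = syn.gen_dendrite_stack(
                    preset, config.shaft_length_um,
                    subject_seed(seed, "em", cond, i))
                _, summary, _ = analyze_stack(stack)
                rows.append({
                    "condition": cond, "dendrite": i,
                    "n_spines": summary.n_spines,
                    "density_per_um": summary.density_per_um,
                    "pct_mushroom": summary.pct_mushroom,
                    "pct_thin": summary.pct_thin,
                    "pct_stubby": summary.pct_stubby,
                    "perforated_pct": summary.perforated_pct,
                    "astro_contacted_pct": summary.astro_contacted_pct})
        df = pd.DataFrame(rows)
        tables["spines"] = df
        for metric in ("density_per_um", "pct_mushroom", "pct_thin",
                       "perforated_pct", "astro_contacted_pct"):
            groups = {c: df.loc[df.condition == c, metric].to_numpy()
                      for c in config.conditions}
            res = one_way_anova_bonferroni(groups, control=config.conditions[0])
            comparisons.append(_comparison_row("em", metric, res))

    if "ephys" in config.arms:
        rows = []
        for cond in config.conditions:
            preset = ps.get_preset("ephys", cond if cond != "control"
                                   else "control")
            sweeps, _ = syn.gen_sweeps(preset, config.n_sweeps, "single",
                                       subject_seed(seed, "ephys", cond, 0))
            for i, sw in enumerate(sweeps):
                f = extract_features(sw, FeatureConfig())
                rows.append({"condition": cond, "sweep": i,
                             "av_amp_mV": f.av_amp_mV,
                             "epsp_peak_mV": f.epsp_peak_mV,
                             "epsp_slope_mV_per_ms": f.epsp_slope_mV_per_ms,
                             "epsp_area_mV_ms": f.epsp_area_mV_ms})
        df = pd.DataFrame(rows)
        tables["ephys"] = df
        for metric in ("av_amp_mV", "epsp_peak_mV"):
            groups = {c: df.loc[df.condition == c, metric].to_numpy()
                      for c in config.conditions}
            res = one_way_anova_bonferroni(groups, control=config.conditions[0])
            comparisons.append(_comparison_row("ephys", metric, res))

    tables["comparisons"] = pd.DataFrame(comparisons)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out_dir / f"{name}.csv", index=False,
                      float_format="%.10g")
    return tables


def _comparison_row(arm: str, metric: str, res: ComparisonResult) -> dict:
    row = {"arm": arm, "metric": metric, "F": res.F_stat,
           "df_between": res.df[0], "df_within": res.df[1],
           "p": res.p_value}
    for (a, b), p in res.pairwise.items():
        row[f"p_{a}_vs_{b}"] = p
    for cond, pct in res.percent_diff.items():
        row[f"pct_diff_{cond}"] = pct
    return row
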