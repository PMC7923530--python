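"""Shared fixtures: analyzed phantom cohorts reused across test modules."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hippoquant.presets import DENDRITE_PRESETS, MEMRI_PRESETS, MemriPreset
from hippoquant.spines import analyze_stack, records_to_frame
from hippoquant.synthetic import gen_dendrite_stack, gen_memri_pair

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: Spec'd cohort: dendrite seeds 1..9 for acceptance, plus 10 to push the
#: pooled spine count past 500 for the recovery invariants.
EM_SEEDS = tuple(range(1, 11))
EM_SHAFT_UM = 12.0


@pytest.fixture(scope="session")
def em_cohorts():
    """Analyzed 10-dendrite cohorts for the myelinated and demyelinated
    presets: per-dendrite summaries, pooled records, and ground truth."""
    out = {}
    for name in ("myelinated", "demyelinated"):
        preset = DENDRITE_PRESETS[name]
        summaries, records, truths = [], [], []
        for seed in EM_SEEDS:
            stack, truth = gen_dendrite_stack(preset, EM_SHAFT_UM, seed)
            recs, summary, diag = analyze_stack(stack)
            df = records_to_frame(recs)
            df["seed"] = seed
            tt = truth.table.sort_values("position_um").reset_index(drop=True)
            tt["seed"] = seed
            assert len(df) == len(tt), f"{name} seed {seed}: {diag}"
            summaries.append(summary)
            records.append(df)
            truths.append(tt)
        out[name] = {
            "summaries": summaries,
            "records": pd.concat(records, ignore_index=True),
            "truth": pd.concat(truths, ignore_index=True),
        }
    return out


@pytest.fixture(scope="session")
def small_memri_preset():
    """A desk-scale control preset on a 28^3 grid for fast null studies."""
    return MemriPreset("small-control", enhanced_fraction=0.6,
                       grid_shape=(28, 28, 28))


@pytest.fixture(scope="session")
def control_pair():
    """One control-preset scan pair with ground truth (seed 1)."""
    return gen_memri_pair(MEMRI_PRESETS["control"], seed=1)
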