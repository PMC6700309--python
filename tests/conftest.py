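import numpy as np
import pandas as pd
import pytest

from biochar_cba.trial import EffectModel, TrialDesign, default_effect_model, generate_trial


@pytest.fixture
def pot_brachiaria():
    return TrialDesign.pot_default("brachiaria")


@pytest.fixture
def pot_panicum():
    return TrialDesign.pot_default("panicum")


@pytest.fixture
def tiny_design():
    """Single factor, 2 replicates, 3 harvests: 2 x 2 x 3 = 12 records."""
    return TrialDesign(grass="brachiaria", factors=("biochar",),
                       replicates=2, harvest_days=(10, 20, 30))


def make_noiseless_model(design, multipliers, baseline=None, seed=0):
    base = baseline or tuple(10.0 for _ in design.harvest_days)
    return EffectModel(
        baseline_per_harvest=base, treatment_multipliers=multipliers,
        subject_sd=0.0, residual_sd=0.0, block_sd=0.0, fresh_noise_sd=0.0,
        seed=seed,
    )


def records_from_means(means):
    """Hand-built harvest table from {label: [per-harvest subject means]}.

    ``means[label]`` is a list over harvests of lists over subjects, so
    oracle values can be computed on a spreadsheet.
    """
    rows = []
    for label, per_harvest in means.items():
        flags = {
            "biochar": int("B" in label.split("+")),
            "fertilizer": int("F" in label.split("+")),
            "inoculant": int("I" in label.split("+")),
        }
        n_subjects = len(per_harvest[0])
        for s in range(n_subjects):
            for h, values in enumerate(per_harvest):
                rows.append({
                    "subject_id": f"{label}-{s + 1}",
                    "block_id": pd.NA,
                    **flags,
                    "harvest_index": h + 1,
                    "harvest_day": (h + 1) * 30,
                    "dry_g": float(values[s]),
                    "fresh_g": float(values[s]) * 4.0,
                })
    df = pd.DataFrame(rows)
    df["block_id"] = df["block_id"].astype("Int64")
    return df


@pytest.fixture
def default_pot_records(pot_brachiaria):
    model = default_effect_model(pot_brachiaria, seed=42)
    return generate_trial(pot_brachiaria, model)
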