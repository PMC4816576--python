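"""Cohort-level evaluation of the calibrated simulator + decoding pipeline.

These routines measure, by running the full pipeline on freshly simulated
cohorts, the quantities the package is calibrated to reproduce: task error
rates and reaction times, the Ne/Pe condition effects recovered by the ERP
path, within- and across-task decoding accuracies, and the type-I-error
behaviour of the permutation test under a label-null simulator.

All randomness derives from a single master seed.
"""

from __future__ import annotations

import numpy as np

from .classify import (
    DEFAULT_PARAMS,
    _cv_counts,
    _seed_for,
    accuracy_rate,
    cv_accuracy,
    repeat_and_aggregate,
)
from .erp_stats import NE_WINDOW, PE_WINDOW, condition_erps, erp_windowed_mean
from .features import FeatureSetSpec, balance_classes, extract_features
from .montage import analysis_montage
from .simulate import make_default_config, make_null_config, simulate_subject

__all__ = [
    "behavioural_summary",
    "effect_recovery",
    "accuracy_bands",
    "null_calibration",
]


def behavioural_summary(n_subjects: int = 50, seed: int = 0) -> dict:
    """Empirical error rates (%) and RT means (ms) of a simulated cohort.

    Only trial metadata matter here, so the voltage noise is switched off to
    keep the simulation cheap.
    """
    cfg = make_default_config(n_subjects=n_subjects, montage=analysis_montage(), seed=seed)
    cfg.noise.white_sd = cfg.noise.pink_sd = cfg.noise.alpha_sd = 0.0
    rates: dict[str, list] = {"flanker": [], "rotation": []}
    rts: dict[tuple[str, str], list] = {}
    for s in range(n_subjects):
        for t_idx, task in enumerate(("flanker", "rotation")):
            meta = simulate_subject(cfg, s, task, _seed_for(seed, s, t_idx)).trial_meta
            rates[task].append(float((meta["response"] == "error").mean()))
            for resp in ("error", "correct"):
                rts.setdefault((task, resp), []).extend(
                    meta.loc[meta["response"] == resp, "rt"].tolist()
                )
    out = {f"error_rate_{task}_pct": 100.0 * float(np.mean(r)) for task, r in rates.items()}
    for (task, resp), values in rts.items():
        out[f"rt_{resp}_{task}_ms"] = float(np.mean(values))
    out["n_subjects"] = n_subjects
    return out


def effect_recovery(n_subjects: int = 200, seed: int = 0, task: str = "flanker") -> dict:
    """Grand-average Ne and Pe error−correct differences (μV magnitudes).

    Simulates ``n_subjects`` subjects of the named task under the default
    configuration, averages each subject's condition ERPs, quantifies the
    windowed means, and averages the per-subject differences — the estimate
    the ERP pipeline produces for the calibrated 10.15 μV (Ne) and 3.97 μV
    (Pe) flanker effects.
    """
    cfg = make_default_config(n_subjects=n_subjects, montage=analysis_montage(), seed=seed)
    ne_diffs, pe_diffs = [], []
    for s in range(n_subjects):
        epochs = simulate_subject(cfg, s, task, _seed_for(seed, s))
        erps = condition_erps(epochs)
        err, corr = erps[(task, "error")], erps[(task, "correct")]
        ne_diffs.append(erp_windowed_mean(err, NE_WINDOW) - erp_windowed_mean(corr, NE_WINDOW))
        pe_diffs.append(erp_windowed_mean(err, PE_WINDOW) - erp_windowed_mean(corr, PE_WINDOW))
    return {
        "ne_difference_uv": float(abs(np.mean(ne_diffs))),
        "pe_difference_uv": float(abs(np.mean(pe_diffs))),
        "n_subjects": n_subjects,
    }


def accuracy_bands(
    n_subjects: int = 10,
    n_repeats: int = 1,
    seed: int = 0,
    n_perm_within: int = 10,
    n_perm_transfer: int = 200,
) -> dict:
    """Within- and across-task combined-feature decoding on a default cohort.

    Returns per-mode mean accuracies (%) across subjects plus the fraction
    of subject x direction transfer analyses that beat chance (accuracy
    > 50 % with mean permutation p < 0.05).
    """
    cfg = make_default_config(n_subjects=n_subjects, montage=analysis_montage(), seed=seed)
    spec = FeatureSetSpec("combined")
    within = {"within-flanker": [], "within-rotation": []}
    transfer = {"flanker-to-rotation": [], "rotation-to-flanker": []}
    significant = 0
    for s in range(n_subjects):
        entry = {
            task: simulate_subject(cfg, s, task, _seed_for(seed, s, t_idx))
            for t_idx, task in enumerate(("flanker", "rotation"))
        }
        for mode, sink in within.items():
            rep = repeat_and_aggregate(
                entry, spec, mode, n_repeats=n_repeats, n_perm=n_perm_within,
                master_seed=_seed_for(seed, s, 10), subject=s,
            )
            sink.append(rep.accuracy_mean_min_max[0])
        for mode, sink in transfer.items():
            rep = repeat_and_aggregate(
                entry, spec, mode, n_repeats=n_repeats, n_perm=n_perm_transfer,
                master_seed=_seed_for(seed, s, 11), subject=s,
            )
            acc = rep.accuracy_mean_min_max[0]
            sink.append(acc)
            if acc > 50.0 and rep.p_mean_min_max[0] < 0.05:
                significant += 1
    return {
        "within_flanker_accuracy_pct": float(np.mean(within["within-flanker"])),
        "within_rotation_accuracy_pct": float(np.mean(within["within-rotation"])),
        "transfer_flanker_to_rotation_accuracy_pct": float(np.mean(transfer["flanker-to-rotation"])),
        "transfer_rotation_to_flanker_accuracy_pct": float(np.mean(transfer["rotation-to-flanker"])),
        "transfer_significant_fraction": significant / (2 * n_subjects),
        "n_subjects": n_subjects,
        "n_repeats": n_repeats,
    }


def null_calibration(
    n_runs: int = 200,
    n_perm: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    trial_range: tuple[int, int] = (160, 200),
) -> dict:
    """Type-I-error behaviour of CV decoding under a label-null simulator.

    Each run simulates one subject from :func:`make_null_config` (labels
    carry no signal), balances the classes, measures the 10-fold CV accuracy
    at fixed default hyperparameters, and runs a label-permutation test.
    Reports the mean CV accuracy (should sit at chance) and the fraction of
    runs rejecting at ``alpha`` (should sit near ``alpha``).

    Two measurement choices keep the estimate clean and cheap: runs use a
    reduced per-subject trial count (200 runs at full size would be slow and
    add nothing to a type-I-error estimate), and each class is trimmed to a
    multiple of the fold count before the CV.  The trimming makes every fold
    exactly class-balanced; without it, k-fold CV on balanced data is biased
    below chance because any residual class surplus in a training split is
    mirrored by a deficit in its held-out fold.
    """
    cfg = make_default_config(n_subjects=1, montage=analysis_montage(), seed=seed)
    for task in cfg.tasks.values():
        task.n_trials_range = trial_range
    null_cfg = make_null_config(cfg)
    spec = FeatureSetSpec("combined")
    accs, rejections = [], 0
    for i in range(n_runs):
        epochs = simulate_subject(null_cfg, i, "flanker", _seed_for(seed, i, 0))
        run_seed = _seed_for(seed, i, 1)
        fm = balance_classes(extract_features(epochs, spec), run_seed)
        # guard the rare draw with fewer than 10 errors per class
        k = min(10, min(fm.class_counts().values()))
        # trim each class to a multiple of k so every fold is exactly balanced
        keep = []
        for label in ("error", "correct"):
            idx = np.flatnonzero(fm.labels == label)
            keep.extend(idx[: (len(idx) // k) * k])
        fm = fm.subset(np.sort(np.asarray(keep)))
        n_corr, n_tot = _cv_counts(fm, fm.labels, DEFAULT_PARAMS, k, run_seed)
        observed = accuracy_rate(n_corr, n_tot)
        rng = np.random.default_rng(_seed_for(seed, i, 2))
        exceed = sum(
            cv_accuracy(fm, rng.permutation(fm.labels), DEFAULT_PARAMS, k, run_seed) >= observed
            for _ in range(n_perm)
        )
        accs.append(observed)
        rejections += (exceed / n_perm) < alpha
    return {
        "null_cv_accuracy_pct": float(np.mean(accs)),
        "null_rejection_rate": rejections / n_runs,
        "n_runs": n_runs,
        "n_perm": n_perm,
    }
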