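"""Self-contained end-to-end validation runs on synthetic cohorts.

These helpers exist so the parameter-recovery and type-I-error behaviour
of the whole pipeline (generator -> preprocessing -> wPLI -> thresholded
graphs -> group statistics) can be measured cheaply and reproducibly.
They run a deliberately scaled-down configuration: one task, the alpha
band only, 14 trials per subject at 250 Hz, a 0.1 s STFT hop (denser
windows compensate the reduced trial count), and no small-world metric
(whose random references dominate runtime and are validated separately).
"""

from __future__ import annotations

import pandas as pd

from .connectivity import epochs_to_band_matrices
from .network import metrics_over_thresholds
from .pipeline import RunConfig, preprocess_subject
from .preprocessing import BAND_BY_NAME
from .stats import compare_cohort
from .synthetic import default_coupling, generate_cohort

SCALED_CONFIG = dict(
    fs=250.0, resample_to=None, bands=("alpha",), tasks=("fist",),
    n_trials=14, with_sw=False, coupling_bands=("alpha",), hop_s=0.1,
    gap_s=0.5,
)
RECOVERY_METRICS = ("cc", "le", "ge")


def scaled_cohort_comparison(
    seed: int,
    patient_attenuation: float = 0.3,
    n_per_group: int = 8,
) -> pd.DataFrame:
    """One scaled pipeline replicate: cohort -> metrics -> FDR comparisons.

    Returns the comparison table for the family {CC, LE, GE} x alpha x fist.
    """
    cfg = RunConfig(seed=seed, n_per_group=n_per_group,
                    patient_attenuation=patient_attenuation, **SCALED_CONFIG)
    coupling = default_coupling(bands=cfg.coupling_bands, noise_sd=cfg.noise_sd,
                                mixing_strength=cfg.mixing_strength)
    cohort = generate_cohort(
        cfg.n_per_group, coupling, patient_attenuation=cfg.patient_attenuation,
        seed=cfg.seed, n_trials=cfg.n_trials, fs=cfg.fs, tasks=cfg.tasks,
        gap_s=cfg.gap_s,
    )
    rows = []
    bands = [BAND_BY_NAME[b] for b in cfg.bands]
    for subject in cohort:
        epochs = preprocess_subject(subject, cfg)
        for task, ep in epochs.items():
            mats = epochs_to_band_matrices(ep, bands, hop_s=cfg.hop_s)
            for band_name, m in mats.items():
                ms = metrics_over_thresholds(m, with_sw=False)
                for metric in RECOVERY_METRICS:
                    rows.append({
                        "subject_id": subject.subject_id,
                        "group": subject.group, "task": task,
                        "band": band_name, "metric": metric,
                        "value": ms.as_dict()[metric],
                    })
    return compare_cohort(pd.DataFrame(rows), cfg.gate_alpha, cfg.fdr_scope)


def recovery_rates(
    seeds,
    patient_attenuation: float = 0.3,
    alpha: float = 0.05,
) -> dict:
    """Fraction of replicate cohorts whose comparisons are FDR-significant
    with patient < control, per metric, plus the overall significant
    fraction (used for null calibration)."""
    hits = {m: 0 for m in RECOVERY_METRICS}
    n_sig = 0
    n_comparisons = 0
    seeds = list(seeds)
    for seed in seeds:
        comp = scaled_cohort_comparison(seed, patient_attenuation)
        n_comparisons += len(comp)
        for row in comp.itertuples():
            sig = row.p_fdr < alpha
            n_sig += int(sig)
            if sig and row.mean_a < row.mean_b:
                hits[row.metric] += 1
    return {
        "rates": {m: hits[m] / len(seeds) for m in RECOVERY_METRICS},
        "significant_fraction": n_sig / n_comparisons,
        "n_replicates": len(seeds),
    }
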