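"""End-to-end convenience: synthetic cohort -> per-subject feature tables.

Chains simulation, light preprocessing (average reference, epoching locked
to the instruction, bad-epoch rejection), windowed feature extraction on
the cluster channels, baseline normalization, and cluster averaging into
the emotion- and neutral-window feature tables used for classification.
"""

from __future__ import annotations

import logging

from .features import WindowedFeatures, extract_all, normalize_features
from .montage import Montage, default_montage
from .pipeline import FeatureTable, cluster_average
from .preprocess import epoch, reject_bad_epochs, rereference_average
from .schedule import TrialSchedule, make_imagery_schedule
from .synth import CohortSpec, simulate_cohort

__all__ = ["cohort_feature_tables", "EPOCH_WINDOW_MS"]

logger = logging.getLogger(__name__)

# instruction-locked epoch covering baseline through the neutral period
EPOCH_WINDOW_MS = (-500.0, 11000.0)


def cohort_feature_tables(
    spec: CohortSpec,
    schedule: TrialSchedule | None = None,
    montage: Montage | None = None,
    reject_abs_uV: float = 100.0,
    reject_prob_z: float = 5.0,
    **extract_kwargs,
) -> tuple[FeatureTable, FeatureTable]:
    """Simulate a cohort and return (emotion, neutral) feature tables.

    Both tables share subjects and group labels; each has the full
    8 x 5 bands x 4 clusters = 160 columns.
    """
    montage = montage or default_montage()
    if schedule is None:
        schedule = make_imagery_schedule(spec.seed)
    cohort = simulate_cohort(spec, schedule=schedule, montage=montage)
    channels = list(montage.cluster_channels)

    parts: list[WindowedFeatures] = []
    groups: dict[str, str] = {}
    for i, (rec, group) in enumerate(cohort):
        sid = f"sub-{i:03d}"
        groups[sid] = group
        rec = rereference_average(rec)
        ep = epoch(rec, "instruction", *EPOCH_WINDOW_MS)
        ep = reject_bad_epochs(ep, abs_uV=reject_abs_uV, prob_z=reject_prob_z)
        wf = extract_all(ep, montage, channels=channels, subject=sid, **extract_kwargs)
        parts.append(normalize_features(wf))
        logger.info("extracted features for %s (%s)", sid, group)

    wf_all = WindowedFeatures.concat(parts)
    emotion = cluster_average(wf_all, montage, "emotion", groups=groups)
    neutral = cluster_average(wf_all, montage, "neutral", groups=groups)
    return emotion, neutral
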