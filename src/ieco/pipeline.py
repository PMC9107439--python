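"""End-to-end convenience layer: cohort -> QC -> metrics -> feature table.

Wraps the per-module operations in the order the full analysis runs:
motion QC (censoring + exclusion), the three voxelwise metrics (ReHo and
ECM on censored frames, fALFF on the unbroken series), network
aggregation, and the ECM-degeneracy exclusion rule.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import encoding, motion as mqc
from .metrics import BoldSeries, MetricMap, SpectralSettings, compute_ecm, compute_falff, compute_reho
from .synthetic import CohortSpec, SyntheticAtlas, SyntheticSubject

__all__ = ["subject_metric_maps", "cohort_feature_table"]


def subject_metric_maps(
    bold: BoldSeries,
    settings: Optional[SpectralSettings] = None,
) -> Dict[str, MetricMap]:
    """ECM, fALFF and ReHo maps for one subject.

    The censor vector on ``bold`` (if any) is honoured by ReHo and ECM;
    fALFF always uses the full series.
    """
    return {
        "ECM": compute_ecm(bold),
        "fALFF": compute_falff(bold, settings),
        "ReHo": compute_reho(bold),
    }


def cohort_feature_table(
    subjects: Sequence[SyntheticSubject],
    atlas: SyntheticAtlas,
    spec: CohortSpec,
    apply_motion_qc: bool = True,
    settings: Optional[SpectralSettings] = None,
) -> Tuple[encoding.FeatureTable, pd.DataFrame]:
    """Run QC and the metric pipeline over a cohort.

    Returns the feature table of retained subjects plus a QC table with
    one row per input subject (mean FD, censored fraction, exclusion
    decision and reason — motion or degenerate ECM).
    """
    rows, sids, groups, qc_rows = [], [], [], []
    for sub in subjects:
        trace = mqc.MotionTrace(params=sub.motion_params)
        fd = mqc.framewise_displacement(trace)
        report = mqc.apply_qc(fd, trace=trace)
        qc_rows.append(
            {
                "subject_id": sub.subject_id,
                "group": sub.group,
                "mean_fd": report.mean_fd,
                "censored_fraction": float((~report.censor).mean()),
                "excluded": report.excluded and apply_motion_qc,
                "reason": report.reason if apply_motion_qc else "qc disabled",
            }
        )
        if apply_motion_qc and report.excluded:
            continue
        censor = report.censor if apply_motion_qc and not report.censor.all() else None
        bold = sub.bold_series(atlas, spec.repetition_time, censor=censor)
        maps = subject_metric_maps(bold, settings)
        rows.append(encoding.aggregate_rois(maps, atlas))
        sids.append(sub.subject_id)
        groups.append(sub.group)

    table = encoding.build_feature_table(rows, sids, groups, atlas.label_names)
    qc = pd.DataFrame(qc_rows)

    degenerate = set(encoding.flag_ecm_degenerate(table))
    if degenerate:
        keep = ~table.data["subject_id"].isin(degenerate)
        table = encoding.FeatureTable(
            data=table.data.loc[keep].reset_index(drop=True),
            network_names=table.network_names,
        )
        qc.loc[qc["subject_id"].isin(degenerate), ["excluded", "reason"]] = [
            True,
            "ECM value of 0 in at least one network",
        ]
    return table, qc
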