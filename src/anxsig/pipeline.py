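"""End-to-end pipeline: preprocess each recording, extract per-epoch
features, split groups on the questionnaire change scores, and run the
whole-task, time-course and PSD-map statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as feat
from . import stats as st
from .io_sync import Recording
from .preprocess import preprocess_recording

log = logging.getLogger(__name__)

#: The eight measures reported in the whole-task results table.
TABLE_MEASURES: tuple[tuple[str, str], ...] = (
    ("hr", "bpm"), ("hrv", "ratio"), ("tonic", "uS"), ("phasic", "uS"),
    ("pupil_left", "mm"), ("pupil_right", "mm"), ("resp_rate", "brpm"),
    ("roll_variance", "dps2"),
)


@dataclass
class PipelineResult:
    assignment: st.GroupAssignment
    feature_tables: dict[str, pd.DataFrame]
    results: list[st.TestResult]
    table: pd.DataFrame
    timecourse_masks: dict[str, st.SignificanceMask]
    roll_psd_comparison: st.SignificanceMask
    eeg_psd_comparison: st.SignificanceMask
    eeg_labels: list[str] = field(default_factory=list)
    psd_freqs: np.ndarray | None = None


def extract_cohort_features(recordings: list[Recording],
                            window_s: float = 30.0, step_s: float = 5.0
                            ) -> dict[str, dict]:
    """Preprocess + feature-extract each recording; returns id -> features."""
    out: dict[str, dict] = {}
    for rec in recordings:
        try:
            proc = preprocess_recording(rec)
            out[rec.participant_id] = feat.extract_features(
                proc, window_s, step_s)
        except ValueError as exc:
            log.warning("skipping participant %s: %s",
                        rec.participant_id, exc)
    if len(out) < 4:
        raise RuntimeError("fewer than 4 participants survived "
                           "preprocessing; aborting")
    return out


def run_pipeline(recordings: list[Recording], alpha: float = st.ALPHA,
                 window_s: float = 30.0, step_s: float = 5.0
                 ) -> PipelineResult:
    """Run the full analysis over a cohort of raw recordings."""
    changes = {rec.participant_id:
               st.gad7_change(rec.gad7_pre, rec.gad7_post)
               for rec in recordings}
    assignment = st.median_split(changes)

    per_part = extract_cohort_features(recordings, window_s, step_s)
    tables = feat.cohort_feature_tables(per_part)

    results, masks = [], {}
    for measure, units in TABLE_MEASURES:
        results.append(st.whole_task_test(tables[measure], assignment,
                                          measure, units))
        masks[measure] = st.timecourse_tests(tables[measure], assignment,
                                             alpha)

    ids = list(per_part)
    freqs = per_part[ids[0]]["psd_freqs"]
    roll_psd = np.stack([per_part[p]["roll_psd"] for p in ids])
    eeg_psd = np.stack([per_part[p]["eeg_psd"] for p in ids])
    roll_cmp = st.psd_group_comparison(roll_psd, freqs, ids, assignment,
                                       "per_bin_roll", alpha)
    eeg_cmp = st.psd_group_comparison(eeg_psd, freqs, ids, assignment,
                                      "per_channel_band_eeg", alpha)
    return PipelineResult(
        assignment=assignment, feature_tables=tables, results=results,
        table=st.results_table(results), timecourse_masks=masks,
        roll_psd_comparison=roll_cmp, eeg_psd_comparison=eeg_cmp,
        eeg_labels=per_part[ids[0]]["eeg_labels"], psd_freqs=freqs)
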