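"""Result persistence and the human-readable run summary."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import MEASURE_UNITS
from .pipeline import PipelineResult


def write_results(res: PipelineResult, out_dir: str | Path) -> Path:
    """Write the results table, per-epoch masks and PSD p-value maps."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.table.to_csv(out / "results_table.csv")

    masks = pd.DataFrame({m: sm.p_raw
                          for m, sm in res.timecourse_masks.items()})
    masks.index.name = "epoch"
    masks.to_csv(out / "timecourse_p_values.csv")
    sig = pd.DataFrame({m: sm.mask.astype(int)
                        for m, sm in res.timecourse_masks.items()})
    sig.index.name = "epoch"
    sig.to_csv(out / "timecourse_significance.csv")

    roll = pd.DataFrame({
        "freq_hz": res.roll_psd_comparison.labels,
        "p_raw": res.roll_psd_comparison.p_raw,
        "p_bh": res.roll_psd_comparison.p_corrected,
        "significant": res.roll_psd_comparison.mask.astype(int)})
    roll.to_csv(out / "roll_psd_pvalues.csv", index=False)

    eeg_rows = []
    for (ch_i, band), praw, pbh, m in zip(
            res.eeg_psd_comparison.labels,
            res.eeg_psd_comparison.p_raw,
            res.eeg_psd_comparison.p_corrected,
            res.eeg_psd_comparison.mask):
        eeg_rows.append({"channel": res.eeg_labels[ch_i], "band": band,
                         "p_raw": praw, "p_bh": pbh,
                         "significant": int(m)})
    pd.DataFrame(eeg_rows).to_csv(out / "eeg_psd_pvalues.csv", index=False)

    groups = pd.DataFrame({
        "participant_id": list(res.assignment.groups),
        "group": list(res.assignment.groups.values()),
        "change_score": [res.assignment.change_scores[p]
                         for p in res.assignment.groups]})
    groups.to_csv(out / "group_assignment.csv", index=False)

    meta = {"alpha": res.timecourse_masks[next(iter(res.timecourse_masks))
                                          ].alpha,
            "n_anxious": len(res.assignment.anxious),
            "n_non_anxious": len(res.assignment.non_anxious)}
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return out


def _sig_windows(mask: np.ndarray, step_s: float = 5.0,
                 window_s: float = 30.0) -> str:
    if not mask.any():
        return "none"
    spans, start = [], None
    for k, m in enumerate(list(mask) + [False]):
        if m and start is None:
            start = k
        elif not m and start is not None:
            spans.append(f"{start * step_s:.0f}-"
                         f"{(k - 1) * step_s + window_s:.0f}s")
            start = None
    return ", ".join(spans)


def summarize(results_dir: str | Path) -> str:
    """Build a plain-text summary from a written results directory."""
    results_dir = Path(results_dir)
    table_path = results_dir / "results_table.csv"
    if not table_path.exists():
        raise FileNotFoundError(
            f"no results_table.csv under {results_dir}; run the pipeline "
            "first")
    table = pd.read_csv(table_path, index_col=0)
    sig = pd.read_csv(results_dir / "timecourse_significance.csv",
                      index_col=0)
    eeg = pd.read_csv(results_dir / "eeg_psd_pvalues.csv")
    roll = pd.read_csv(results_dir / "roll_psd_pvalues.csv")

    lines = ["Group comparison summary", "=" * 24, ""]
    for measure, row in table.iterrows():
        name = measure.split(" [")[0]
        lines.append(
            f"{measure}: anx {row['mean_anx']:.3f} "
            f"vs non-anx {row['mean_non_anx']:.3f}; "
            f"W={row['rank_sum']:.0f}, p={row['p_value']:.4g}, "
            f"d={row['cohens_d']:.3f}")
        if name in sig.columns:
            lines.append("  significant epochs (uncorrected): "
                         + _sig_windows(sig[name].to_numpy().astype(bool)))
    n_roll = int(roll["significant"].sum())
    n_eeg = int(eeg["significant"].sum())
    lines += ["",
              f"Head-roll PSD: {n_roll}/{len(roll)} bins significant "
              "after BH correction",
              f"EEG PSD: {n_eeg}/{len(eeg)} channel x band cells "
              "significant after BH correction"]
    units_note = ", ".join(f"{m} [{u}]" for m, u in MEASURE_UNITS.items())
    lines += ["", f"Measures and units: {units_note}"]
    return "\n".join(lines) + "\n"
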