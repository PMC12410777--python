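"""Assemble the human-readable summary of the pipeline run: per-measure
group descriptives, rank-sum p-values, effect sizes, significant epoch
windows, and the PSD-map discovery counts.

Reads results/analysis/ written by 02_run_pipeline.py and writes
results/summary.txt.
"""

from pathlib import Path

from anxsig.report import summarize

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    text = summarize(RESULTS / "analysis")
    (RESULTS / "summary.txt").write_text(text)
    print(text)
    print(f"summary written to {RESULTS / 'summary.txt'}")


if __name__ == "__main__":
    main()
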