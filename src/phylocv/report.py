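"""Tab-separated cross-validation report files.

One detail row per (model, replicate) with its score and relative score,
plus one summary row per model carrying the mean and standard deviation
over replicates.  Floats are written with 17 significant digits so a
written report re-reads to identical numeric values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from phylocv.crossval import CVReport

_COLUMNS = ["model", "replicate", "cv_score", "delta_vs_reference",
            "score_mean", "score_sd", "delta_mean", "delta_sd"]


def write_cv_report(report: CVReport, path) -> None:
    """Write a CVReport as a round-trippable TSV table."""
    path = Path(path)
    rows = []
    deltas = report.deltas() if report.scores else {}
    summary = report.summary() if report.scores else {}
    for m in report.models:
        for r in range(report.n_replicates):
            rows.append({"model": m, "replicate": str(r + 1),
                         "cv_score": report.scores[m][r],
                         "delta_vs_reference": deltas[m][r]})
        rows.append({"model": m, "replicate": "summary", **summary[m]})
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    with path.open("w") as fh:
        fh.write(f"# phylocv cv report\n# reference: {report.reference}\n")
        if report.split_ids:
            fh.write(f"# split_ids: {','.join(report.split_ids)}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_cv_report(path) -> CVReport:
    """Re-read a report written by :func:`write_cv_report`."""
    path = Path(path)
    reference = ""
    split_ids: list[str] = []
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# reference:"):
                reference = line.split(":", 1)[1].strip()
            elif line.startswith("# split_ids:"):
                split_ids = line.split(":", 1)[1].strip().split(",")
    frame = pd.read_csv(path, sep="\t", comment="#",
                        dtype={"model": str, "replicate": str})
    scores: dict[str, np.ndarray] = {}
    if len(frame):
        detail = frame[frame["replicate"] != "summary"]
        for m, grp in detail.groupby("model", sort=False):
            order = grp["replicate"].astype(int).argsort()
            scores[m] = grp["cv_score"].to_numpy()[order]
    return CVReport(scores=scores, reference=reference or
                    (next(iter(scores)) if scores else ""),
                    split_ids=split_ids)
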