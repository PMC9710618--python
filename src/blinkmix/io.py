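"""Reading blink-count files and writing fit reports.

Input is deliberately minimal: a one-column CSV/TSV text file with one
integer blink count per record and an optional single header line
(auto-detected when the first row is non-numeric).  Fit reports are JSON
with full-precision parameters, enough metadata (version, seed, input
digest) to reproduce a run bit-for-bit, and are round-trippable back
into :class:`~blinkmix.model.MixtureParams`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .em import FitResult
from .labeling import CorrectedWeights
from .model import BlinkDataset, MixtureParams

__all__ = ["read_blink_counts", "write_fit_report", "read_fit_report", "file_digest"]


def read_blink_counts(path) -> BlinkDataset:
    """Load a one-count-per-record CSV/TSV file into a BlinkDataset."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    lines = path.read_text().splitlines()
    rows = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
    if not rows:
        raise ValueError(f"{path} is empty")
    start = 0
    first = rows[0][1].split(",")[0].split("\t")[0].strip()
    try:
        float(first)
    except ValueError:
        start = 1  # header line
    if start == len(rows):
        raise ValueError(f"{path} contains a header but no data")
    counts = []
    for lineno, raw in rows[start:]:
        token = raw.split(",")[0].split("\t")[0].strip()
        try:
            value = float(token)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value {token!r}") from exc
        if value != int(value):
            raise ValueError(f"{path}:{lineno}: blink count must be an integer, got {token}")
        if value < 1:
            raise ValueError(f"{path}:{lineno}: blink count must be >= 1, got {token}")
        counts.append(int(value))
    return BlinkDataset(np.asarray(counts, dtype=np.int64))


def file_digest(path) -> str:
    """SHA-256 digest of a file's bytes, for provenance logging."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_fit_report(
    result: FitResult,
    path,
    corrected: CorrectedWeights | None = None,
    theta: float | None = None,
    seed: int | None = None,
    input_digest: str | None = None,
) -> dict:
    """Serialize a fit (and optional labeling correction) to JSON.

    Numbers are stored at full double precision so a reader can
    reconstruct the fitted MixtureParams exactly.  Returns the report
    dict that was written.
    """
    report = {
        "blinkmix_version": __version__,
        "h": result.params.h,
        "weights_apparent": result.params.weights.tolist(),
        "lam": result.params.lam,
        "loglik": result.loglik,
        "aic": result.aic,
        "n_iter": result.n_iter,
        "converged": bool(result.converged),
        "restarts_used": result.restarts_used,
        "seed": seed,
        "input_sha256": input_digest,
    }
    if corrected is not None:
        report["theta"] = theta
        report["weights_corrected"] = corrected.true_weights.tolist()
        report["correction_clipped"] = bool(corrected.clipped)
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
    return report


def read_fit_report(path) -> tuple[dict, MixtureParams]:
    """Load a JSON fit report and rebuild the fitted parameters."""
    report = json.loads(Path(path).read_text())
    params = MixtureParams(
        h=int(report["h"]),
        weights=np.asarray(report["weights_apparent"], dtype=float),
        lam=float(report["lam"]),
    )
    return report, params
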