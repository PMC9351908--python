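"""ECG epoch container and CSV interchange.

The in-memory unit is :class:`EcgEpoch`: an ordered set of equal-length
lead traces in microvolts at a common sampling rate.  Interchange format is
plain CSV — a header row of lead names, one row per sample, optional
leading ``#`` provenance comments.  Sampling rate travels in a ``# fs=``
comment (and may be overridden at read time).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EcgEpoch",
    "read_record",
    "write_record",
    "select_epoch",
    "select_leads",
    "choose_epoch_start",
]

#: Case/alias-insensitive lead label normalization ("lead v1" == "V1").
def _norm_lead(label: str) -> str:
    s = str(label).strip().upper()
    if s.startswith("LEAD "):
        s = s[5:]
    return s


@dataclass
class EcgEpoch:
    """Multi-lead ECG segment: amplitudes in uV, ``fs`` in Hz, ``t0`` the
    epoch's start offset (s) within its source record."""

    leads: list[str]
    fs: float
    samples: dict[str, np.ndarray]
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lengths = {len(self.samples[l]) for l in self.leads}
        if len(lengths) > 1:
            raise ValueError(f"leads have unequal lengths: {sorted(lengths)}")
        for l in self.leads:
            if not np.all(np.isfinite(self.samples[l])):
                raise ValueError(f"non-finite amplitudes in lead {l}")

    @property
    def n_samples(self) -> int:
        return len(self.samples[self.leads[0]]) if self.leads else 0

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def lead(self, label: str) -> np.ndarray:
        """Fetch one lead's trace, alias-insensitively."""
        want = _norm_lead(label)
        for l in self.leads:
            if _norm_lead(l) == want:
                return self.samples[l]
        raise KeyError(f"lead {label!r} not present (have {self.leads})")


def write_record(
    epoch: EcgEpoch, path: str | Path, header_comments: list[str] | None = None
) -> None:
    """Write an epoch as CSV: ``# fs=...`` comment, lead-name header, one
    row per sample (amplitudes in uV)."""
    path = Path(path)
    lines = [f"# fs={epoch.fs:g}", f"# t0={epoch.t0:g}", "# units=uV"]
    lines += [f"# {c}" for c in (header_comments or [])]
    df = pd.DataFrame({l: epoch.samples[l] for l in epoch.leads})
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def read_record(
    path: str | Path,
    format: str = "csv",
    fs: float | None = None,
    scale_to_uv: float = 1.0,
) -> EcgEpoch:
    """Read a record into an :class:`EcgEpoch` (t0 = 0).

    ``format`` must be ``"csv"``: columns are leads (header row of lead
    names), amplitudes assumed uV unless ``scale_to_uv`` says otherwise
    (e.g. 1000 for a file in mV).  ``fs`` overrides / supplies the sampling
    rate if the file carries no ``# fs=`` comment.
    """
    if format.lower() != "csv":
        raise ValueError(
            f"unsupported format {format!r}: CSV is the supported interchange format"
        )
    path = Path(path)
    file_fs = None
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("fs="):
                file_fs = float(body[3:])
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    if fs is None:
        fs = file_fs
    if fs is None:
        raise ValueError(f"{path}: sampling rate unresolvable (no '# fs=' and no fs argument)")
    leads = [str(c) for c in df.columns]
    if any(c.strip() == "" or c.startswith("Unnamed") for c in leads):
        raise ValueError(f"{path}: missing lead names in header row")
    samples = {l: df[l].to_numpy(dtype=float) * scale_to_uv for l in leads}
    return EcgEpoch(leads=leads, fs=float(fs), samples=samples, t0=0.0)


def select_epoch(epoch: EcgEpoch, start: float, duration: float = 10.0) -> EcgEpoch:
    """Contiguous time slice ``[start, start+duration)`` seconds; t0 shifts."""
    if start < 0:
        raise ValueError("start must be >= 0")
    i0 = int(round(start * epoch.fs))
    i1 = i0 + int(round(duration * epoch.fs))
    if i1 > epoch.n_samples:
        raise ValueError(
            f"window [{start}, {start + duration}) s exceeds record length "
            f"{epoch.duration:g} s"
        )
    samples = {l: epoch.samples[l][i0:i1] for l in epoch.leads}
    return EcgEpoch(leads=list(epoch.leads), fs=epoch.fs, samples=samples,
                    t0=epoch.t0 + start)


def select_leads(epoch: EcgEpoch, wanted=("I", "II", "V1", "V6")) -> EcgEpoch:
    """Restrict to the requested leads, in the requested order.

    Matching is case- and alias-insensitive; an absent lead raises an error
    naming it.
    """
    norm_map = {_norm_lead(l): l for l in epoch.leads}
    out_leads, samples = [], {}
    for w in wanted:
        key = _norm_lead(w)
        if key not in norm_map:
            raise KeyError(f"requested lead {w!r} not in record (have {epoch.leads})")
        src = norm_map[key]
        out_leads.append(src)
        samples[src] = epoch.samples[src]
    return EcgEpoch(leads=out_leads, fs=epoch.fs, samples=samples, t0=epoch.t0)


def choose_epoch_start(
    epoch: EcgEpoch, duration: float = 10.0, stride: float = 1.0,
    clip_uv: float = 2000.0,
) -> float:
    """Pick the analysis-window start minimizing a simple artifact score.

    The score of a candidate window is the fraction of samples beyond
    ±``clip_uv`` plus the fraction of exactly-saturated (running-max)
    samples, summed over leads; the earliest minimizer wins, so the choice
    is deterministic.
    """
    if epoch.duration < duration:
        raise ValueError("record shorter than requested epoch")
    best_start, best_score = 0.0, np.inf
    start = 0.0
    while start + duration <= epoch.duration + 1e-9:
        sl = select_epoch(epoch, start, min(duration, epoch.duration - start))
        score = 0.0
        for l in sl.leads:
            x = sl.samples[l]
            score += float(np.mean(np.abs(x) > clip_uv))
            score += float(np.mean(x == np.max(np.abs(x))))
        if score < best_score - 1e-12:
            best_score, best_start = score, start
        start += stride
    return best_start
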