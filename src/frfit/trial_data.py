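"""Data model and I/O for predation-trial records.

A trial is one arena-day: a single predator exposed for ``t_expose`` days to
``n0`` focal prey (whitefly nymphs, parasitized or not) plus ``ap_offered``
alternative prey (aphids); ``ne`` and ``ap_consumed`` record what was eaten.

The on-disk format is a plain UTF-8 CSV with the required header
``n0,ne,ap_offered,ap_consumed,igp,treatment,replicate,t_expose``; extra
columns are preserved in the set-level metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "REQUIRED_COLUMNS",
    "PredationTrial",
    "TrialSet",
    "read_trials",
    "write_trials",
    "summarize_consumption",
]

REQUIRED_COLUMNS = (
    "n0",
    "ne",
    "ap_offered",
    "ap_consumed",
    "igp",
    "treatment",
    "replicate",
    "t_expose",
)

IGP_CONTEXTS = ("non-parasitized", "parasitized")


@dataclass(frozen=True)
class PredationTrial:
    """One arena-day record.

    Attributes
    ----------
    n0 : initial focal-prey density (count).
    ne : focal prey consumed (count), ``0 <= ne <= n0``.
    ap_offered, ap_consumed : alternative prey offered / consumed (counts).
    igp : context flag, ``"non-parasitized"`` or ``"parasitized"`` focal prey.
    treatment : alternative-prey treatment label (e.g. ``"No AP"``).
    replicate : block identifier (experimentation day).
    t_expose : exposure time in days (24 h = 1.0).
    """

    n0: int
    ne: int
    ap_offered: int = 0
    ap_consumed: int = 0
    igp: str = "non-parasitized"
    treatment: str = "No AP"
    replicate: str = "1"
    t_expose: float = 1.0

    def __post_init__(self) -> None:
        problems = self.problems()
        if problems:
            raise ValidationError("; ".join(problems))

    def problems(self) -> List[str]:
        """Human-readable list of invariant violations (empty if valid)."""
        out = []
        if self.n0 < 1:
            out.append(f"n0 must be >= 1 (got {self.n0})")
        if not 0 <= self.ne <= self.n0:
            out.append(f"ne must satisfy 0 <= ne <= n0 (got ne={self.ne}, n0={self.n0})")
        if self.ap_offered < 0:
            out.append(f"ap_offered must be >= 0 (got {self.ap_offered})")
        if not 0 <= self.ap_consumed <= max(self.ap_offered, 0):
            out.append(
                "ap_consumed must satisfy 0 <= ap_consumed <= ap_offered "
                f"(got {self.ap_consumed}, offered {self.ap_offered})"
            )
        if self.igp not in IGP_CONTEXTS:
            out.append(f"igp must be one of {IGP_CONTEXTS} (got {self.igp!r})")
        if not self.t_expose > 0:
            out.append(f"t_expose must be > 0 (got {self.t_expose})")
        return out


@dataclass
class TrialSet:
    """An ordered collection of predation trials plus free-form metadata."""

    trials: List[PredationTrial] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[PredationTrial]:
        return iter(self.trials)

    @property
    def densities(self) -> np.ndarray:
        """Sorted unique initial focal-prey densities."""
        return np.unique([tr.n0 for tr in self.trials])

    @property
    def t_expose(self) -> float:
        """Common exposure time; raises if trials disagree."""
        ts = {tr.t_expose for tr in self.trials}
        if len(ts) != 1:
            raise ValidationError(
                f"trials do not share a single exposure time: {sorted(ts)}"
            )
        return ts.pop()

    def require_nonempty(self) -> None:
        if not self.trials:
            raise ValidationError("TrialSet is empty")

    def subset(self, igp: Optional[str] = None, treatment: Optional[str] = None) -> "TrialSet":
        """Trials matching the given context and/or treatment label."""
        keep = [
            tr
            for tr in self.trials
            if (igp is None or tr.igp == igp)
            and (treatment is None or tr.treatment == treatment)
        ]
        return TrialSet(keep, dict(self.metadata))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {col: getattr(tr, col) for col in REQUIRED_COLUMNS}
                for tr in self.trials
            ],
            columns=list(REQUIRED_COLUMNS),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: Optional[dict] = None) -> "TrialSet":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        trials: List[PredationTrial] = []
        bad: List[str] = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            try:
                tr = PredationTrial(
                    n0=int(getattr(row, "n0")),
                    ne=int(getattr(row, "ne")),
                    ap_offered=int(getattr(row, "ap_offered")),
                    ap_consumed=int(getattr(row, "ap_consumed")),
                    igp=str(getattr(row, "igp")),
                    treatment=str(getattr(row, "treatment")),
                    replicate=str(getattr(row, "replicate")),
                    t_expose=float(getattr(row, "t_expose")),
                )
            except (ValidationError, ValueError) as exc:
                bad.append(f"row {i}: {exc}")
            else:
                trials.append(tr)
        if bad:
            raise ValidationError("invalid trial record(s): " + " | ".join(bad))
        extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
        meta = dict(metadata or {})
        if extra:
            meta.setdefault("extra_columns", {})
            for c in extra:
                meta["extra_columns"][c] = df[c].tolist()
        return cls(trials, meta)


def read_trials(path, format: str = "csv") -> TrialSet:
    """Read a validated :class:`TrialSet` from a trials CSV.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` naming the offending row(s) for invariant
    violations. A ``<name>.meta.json`` sidecar, if present, is loaded into
    the set metadata.
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    df = pd.read_csv(path)
    meta: dict = {"source": str(path)}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return TrialSet.from_frame(df, meta)


def write_trials(ts: TrialSet, path, metadata_sidecar: bool = True) -> Path:
    """Write a :class:`TrialSet` to CSV (plus a JSON metadata sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ts.to_frame().to_csv(path, index=False)
    if metadata_sidecar and ts.metadata:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(_jsonable(ts.metadata), indent=2, sort_keys=True))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def summarize_consumption(ts: TrialSet) -> pd.DataFrame:
    """Per (context, treatment, density) consumption summary.

    Returns one row per cell with the mean and standard error of focal-prey
    consumption, of alternative-prey consumption, and their sum
    (``total_consumed = mean_ne + mean_ap``). The SE is the sample standard
    deviation over ``sqrt(n)``; cells with a single trial report a missing SE
    (the sample SD is undefined at n = 1).
    """
    ts.require_nonempty()
    df = ts.to_frame()
    rows = []
    grouped = df.groupby(["igp", "treatment", "n0"], sort=True)
    for (igp, treatment, n0), cell in grouped:
        n = len(cell)

        def _se(x: pd.Series) -> float:
            return float(x.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")

        mean_ne = float(cell["ne"].mean())
        mean_ap = float(cell["ap_consumed"].mean())
        rows.append(
            {
                "igp": igp,
                "treatment": treatment,
                "n0": int(n0),
                "n": n,
                "mean_ne": mean_ne,
                "se_ne": _se(cell["ne"]),
                "mean_ap_consumed": mean_ap,
                "se_ap_consumed": _se(cell["ap_consumed"]),
                "total_consumed": mean_ne + mean_ap,
            }
        )
    return pd.DataFrame(rows)
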