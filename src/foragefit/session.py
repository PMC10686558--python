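"""Session data model, CSV I/O and lagged history-predictor construction.

A behavioral session is a sequence of two-alternative choice trials with
binary reward outcomes, organized into reward-probability blocks, with
optional optogenetic-inactivation and validity flags.  Choice is coded as
a side label ("L"/"R"); throughout the package the LEFT port is the
positive class, so models predict P(left).

The history predictors are the signed rewarded-choice and unrewarded-choice
regressors used by every downstream model:

    RewC(t) = +1 rewarded left, -1 rewarded right, 0 otherwise
    UnrC(t) = +1 unrewarded left, -1 unrewarded right, 0 otherwise

Lags are counted over *valid* trials only: alarm/miss trials are spliced
out of the sequence before any lag structure is built.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SESSION_COLUMNS = ["trial", "choice", "reward", "block", "inactivation", "valid"]

CHOICE_SIGN = {"L": 1, "R": -1}


class SessionFormatError(ValueError):
    """Raised when a session file or table violates the documented format."""


@dataclass
class SessionTable:
    """One behavioral session.

    Parameters
    ----------
    choice : array of "L"/"R" strings (may be "" on invalid trials)
    reward : binary array, 0 on invalid trials
    block : integer block ids
    inactivation : binary flags
    valid : binary flags (alarm/miss trials are invalid)
    """

    choice: np.ndarray
    reward: np.ndarray
    block: np.ndarray
    inactivation: np.ndarray
    valid: np.ndarray
    trial: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.choice = np.asarray(self.choice, dtype=object)
        n = len(self.choice)
        self.reward = np.asarray(self.reward, dtype=int)
        self.block = np.asarray(self.block, dtype=int)
        self.inactivation = np.asarray(self.inactivation, dtype=int)
        self.valid = np.asarray(self.valid, dtype=int)
        if self.trial is None:
            self.trial = np.arange(n)
        self.trial = np.asarray(self.trial, dtype=int)
        self._validate()

    def _validate(self):
        n = len(self.choice)
        for name in ("reward", "block", "inactivation", "valid", "trial"):
            if len(getattr(self, name)) != n:
                raise SessionFormatError(f"column '{name}' has wrong length")
        bad = np.where(~np.isin(self.reward, (0, 1)))[0]
        if bad.size:
            raise SessionFormatError(f"non-binary reward at row {bad[0]}")
        bad = np.where(~np.isin(self.inactivation, (0, 1)))[0]
        if bad.size:
            raise SessionFormatError(f"non-binary inactivation at row {bad[0]}")
        bad = np.where(~np.isin(self.valid, (0, 1)))[0]
        if bad.size:
            raise SessionFormatError(f"non-binary valid flag at row {bad[0]}")
        for i in np.where(self.valid == 1)[0]:
            if self.choice[i] not in CHOICE_SIGN:
                raise SessionFormatError(
                    f"unknown side token {self.choice[i]!r} at row {i}"
                )
        if np.any((self.valid == 0) & (self.reward != 0)):
            row = int(np.where((self.valid == 0) & (self.reward != 0))[0][0])
            raise SessionFormatError(f"reward on invalid trial at row {row}")
        if n > 1 and np.any(np.diff(self.trial) <= 0):
            raise SessionFormatError("trial indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.choice)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_trials(self) -> "SessionTable":
        """Return the session restricted to valid trials (lag structure spliced)."""
        m = self.valid == 1
        return SessionTable(
            choice=self.choice[m],
            reward=self.reward[m],
            block=self.block[m],
            inactivation=self.inactivation[m],
            valid=self.valid[m],
            trial=self.trial[m],
        )

    def choice_sign(self) -> np.ndarray:
        """Signed choice over valid trials: +1 left, -1 right."""
        vt = self.valid_trials()
        return np.array([CHOICE_SIGN[c] for c in vt.choice], dtype=float)

    def subset(self, mask: np.ndarray) -> "SessionTable":
        """Row subset by boolean mask (keeps original trial indices)."""
        mask = np.asarray(mask, dtype=bool)
        return SessionTable(
            choice=self.choice[mask],
            reward=self.reward[mask],
            block=self.block[mask],
            inactivation=self.inactivation[mask],
            valid=self.valid[mask],
            trial=self.trial[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trial,
                "choice": ["" if c is None else str(c) for c in self.choice],
                "reward": self.reward,
                "block": self.block,
                "inactivation": self.inactivation,
                "valid": self.valid,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SessionTable":
        missing = [c for c in SESSION_COLUMNS if c not in df.columns]
        if missing:
            raise SessionFormatError(f"missing column(s): {', '.join(missing)}")
        choice = df["choice"].fillna("").astype(str).str.strip().values
        return cls(
            choice=choice,
            reward=df["reward"].values,
            block=df["block"].values,
            inactivation=df["inactivation"].values,
            valid=df["valid"].values,
            trial=df["trial"].values,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SessionTable):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in ("choice", "reward", "block", "inactivation", "valid", "trial")
        )


@dataclass
class HistoryDesign:
    """Lagged history design matrix over valid trials.

    rewc, unrc : (n_valid, n_lags) matrices, column i holds lag i+1
    y : response, 1 for left choice, 0 for right
    """

    rewc: np.ndarray
    unrc: np.ndarray
    y: np.ndarray

    @property
    def n_lags(self) -> int:
        return self.rewc.shape[1]


@dataclass
class NeuralSession:
    """Trial-mean (ready-period) activity for one imaged population.

    activity : (n_cells, n_valid_trials) matrix, z-scored per cell
    """

    activity: np.ndarray
    area: str = ""
    session_id: str = ""

    def __post_init__(self):
        self.activity = np.atleast_2d(np.asarray(self.activity, dtype=float))

    @property
    def n_cells(self) -> int:
        return self.activity.shape[0]

    @property
    def n_trials(self) -> int:
        return self.activity.shape[1]


def read_session(path) -> SessionTable:
    """Read a session CSV (header: trial,choice,reward,block,inactivation,valid)."""
    df = pd.read_csv(path, dtype={"choice": str})
    try:
        return SessionTable.from_frame(df)
    except SessionFormatError as e:
        raise SessionFormatError(f"{path}: {e}") from None


def write_session(table: SessionTable, path) -> None:
    """Write a session CSV with deterministic column order; round-trips exactly."""
    table.to_frame().to_csv(path, index=False)


def read_neural(path) -> NeuralSession:
    """Read a cells x trials activity matrix (CSV, no header) + JSON sidecar."""
    path = Path(path)
    activity = np.loadtxt(path, delimiter=",", ndmin=2)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return NeuralSession(
        activity=activity,
        area=meta.get("area", ""),
        session_id=meta.get("session_id", ""),
    )


def write_neural(ns: NeuralSession, path) -> None:
    path = Path(path)
    np.savetxt(path, ns.activity, delimiter=",")
    path.with_suffix(".json").write_text(
        json.dumps({"area": ns.area, "session_id": ns.session_id})
    )


def history_signals(table: SessionTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-valid-trial (rewc, unrc, y) signals, before lagging.

    rewc[t] = choice_sign[t] * reward[t]; unrc[t] = choice_sign[t] * (1 - reward[t]).
    """
    vt = table.valid_trials()
    sign = np.array([CHOICE_SIGN[c] for c in vt.choice], dtype=float)
    r = vt.reward.astype(float)
    return sign * r, sign * (1.0 - r), (sign > 0).astype(float)


def lag_matrix(signal: np.ndarray, n_lags: int) -> np.ndarray:
    """Stack lagged copies of a per-trial signal; pre-session lags are 0."""
    n = len(signal)
    out = np.zeros((n, n_lags))
    for i in range(1, n_lags + 1):
        out[i:, i - 1] = signal[:-i] if i < n else []
    return out


def encode_history(table: SessionTable, n_lags: int) -> HistoryDesign:
    """Build the lagged RewC/UnrC design for choice regression.

    Lags count back over valid trials only; lags reaching before the session
    start are coded 0, so all valid trials are retained as responses.
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    if table.n_valid < n_lags + 1:
        raise ValueError(
            f"need at least n_lags+1={n_lags + 1} valid trials, got {table.n_valid}"
        )
    rewc, unrc, y = history_signals(table)
    return HistoryDesign(
        rewc=lag_matrix(rewc, n_lags), unrc=lag_matrix(unrc, n_lags), y=y
    )
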