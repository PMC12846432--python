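"""Data model, CSV I/O and validation for experimental hut trial records.

An experimental hut trial (EHT) counts wild, free-flying mosquitoes that
enter baited huts fitted with candidate bed nets.  Every hut-night yields
a fully cross-classified 12-cell count matrix:

    location  (room, veranda trap, window trap)
  x blood-fed (no, yes)
  x status    (alive, dead)

Table-style endpoints (exophily, blood feeding, mortality, deterrence)
are all margins of this matrix, but the full grid is stored so that the
simulator and any finer endpoint can use it losslessly.

The trial design rotates treatment arms between huts in weekly periods
following a Latin square, and rotates baits (cattle, in zoophilic
settings) daily; :meth:`TrialDataset.check_latin_square` verifies the
arm-rotation balance on recorded data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LOCATIONS",
    "FED_LEVELS",
    "STATUS_LEVELS",
    "COUNT_COLUMNS",
    "META_COLUMNS",
    "TrialValidationError",
    "HutNightRecord",
    "ArmTotals",
    "TrialDataset",
    "read_trial_csv",
]

LOCATIONS = ("room", "ver", "win")
FED_LEVELS = ("unfed", "fed")
STATUS_LEVELS = ("alive", "dead")

#: Canonical count-column order: location-major, then fed, then status.
COUNT_COLUMNS = tuple(
    f"{loc}_{fed}_{status}"
    for loc in LOCATIONS
    for fed in FED_LEVELS
    for status in STATUS_LEVELS
)
META_COLUMNS = ("night", "hut", "bait", "arm")


class TrialValidationError(ValueError):
    """A trial record or file violates the data contract.

    The message names the offending row (1-based, excluding the header)
    and cell where applicable.
    """


@dataclass(frozen=True)
class HutNightRecord:
    """One hut x night observation with its 12-cell count matrix.

    ``counts`` is indexed ``[location, fed, dead]`` with the level order
    of :data:`LOCATIONS`, :data:`FED_LEVELS`, :data:`STATUS_LEVELS`.
    """

    night: int
    hut: str
    bait: str
    arm: str
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64).reshape(3, 2, 2)
        if (counts < 0).any():
            raise TrialValidationError("negative count in hut-night record")
        if self.night < 1:
            raise TrialValidationError(f"night index must be >= 1, got {self.night}")
        object.__setattr__(self, "counts", counts)

    @property
    def caught(self) -> int:
        return int(self.counts.sum())

    @property
    def exited(self) -> int:
        """Mosquitoes found in veranda or window traps."""
        return int(self.counts[1:].sum())

    @property
    def fed(self) -> int:
        return int(self.counts[:, 1, :].sum())

    @property
    def dead(self) -> int:
        """Dead regardless of location (room, veranda or window trap)."""
        return int(self.counts[:, :, 1].sum())

    def as_row(self) -> dict:
        row = {"night": self.night, "hut": self.hut, "bait": self.bait, "arm": self.arm}
        row.update(zip(COUNT_COLUMNS, self.counts.ravel().tolist()))
        return row


@dataclass(frozen=True)
class ArmTotals:
    """Per-arm totals over all hut-nights: the raw material of every
    entomological endpoint (Tu/Tt, Bu/Bt, Ku/Kt in the usual notation)."""

    arm: str
    caught: int
    exited: int
    fed: int
    dead: int
    nights: int

    def __post_init__(self) -> None:
        for name in ("exited", "fed", "dead"):
            if getattr(self, name) > self.caught:
                raise TrialValidationError(
                    f"{name} ({getattr(self, name)}) exceeds caught ({self.caught}) for arm {self.arm!r}"
                )


def _validate_frame(frame: pd.DataFrame, allowed_arms: Sequence[str] | None) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS + COUNT_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialValidationError(f"missing required columns: {missing}")
    frame = frame.loc[:, list(META_COLUMNS + COUNT_COLUMNS)].copy()

    for col in ("night",) + COUNT_COLUMNS:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() | (coerced != np.floor(coerced))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise TrialValidationError(f"row {row}: column {col!r} is not an integer")
        frame[col] = coerced.astype(np.int64)
    for col in ("hut", "bait", "arm"):
        frame[col] = frame[col].astype(str)

    for col in COUNT_COLUMNS:
        neg = frame[col] < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0]) + 1
            raise TrialValidationError(f"row {row}: negative count in cell {col!r}")
    if (frame["night"] < 1).any():
        row = int(np.flatnonzero((frame["night"] < 1).to_numpy())[0]) + 1
        raise TrialValidationError(f"row {row}: night index must be >= 1")

    dup = frame.duplicated(subset=["hut", "night"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 1
        hut, night = frame.iloc[row - 1][["hut", "night"]]
        raise TrialValidationError(f"row {row}: duplicate (hut, night) pair ({hut!r}, {night})")

    if allowed_arms is not None:
        unknown = ~frame["arm"].isin(list(allowed_arms))
        if unknown.any():
            row = int(np.flatnonzero(unknown.to_numpy())[0]) + 1
            raise TrialValidationError(
                f"row {row}: unknown arm code {frame.iloc[row - 1]['arm']!r}"
            )
    return frame.reset_index(drop=True)


class TrialDataset:
    """Validated collection of :class:`HutNightRecord` rows.

    Wraps a :class:`pandas.DataFrame` in the canonical column order.  Row
    order is preserved exactly as read or generated.
    """

    def __init__(self, frame: pd.DataFrame, allowed_arms: Sequence[str] | None = None):
        self.frame = _validate_frame(frame, allowed_arms)

    # -- construction ------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[HutNightRecord]) -> "TrialDataset":
        rows = [r.as_row() for r in records]
        if not rows:
            frame = pd.DataFrame(columns=list(META_COLUMNS + COUNT_COLUMNS))
            frame["night"] = frame["night"].astype(np.int64)
            for col in COUNT_COLUMNS:
                frame[col] = frame[col].astype(np.int64)
            return cls(frame)
        return cls(pd.DataFrame(rows))

    @classmethod
    def concat(cls, datasets: Sequence["TrialDataset"]) -> "TrialDataset":
        return cls(pd.concat([d.frame for d in datasets], ignore_index=True))

    # -- basic protocol ----------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[HutNightRecord]:
        for _, row in self.frame.iterrows():
            yield HutNightRecord(
                night=int(row["night"]),
                hut=row["hut"],
                bait=row["bait"],
                arm=row["arm"],
                counts=row[list(COUNT_COLUMNS)].to_numpy(dtype=np.int64),
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialDataset):
            return NotImplemented
        return self.frame.equals(other.frame)

    @property
    def arms(self) -> list[str]:
        return sorted(self.frame["arm"].unique().tolist())

    # -- aggregation -------------------------------------------------

    def arm_totals(self, arm: str) -> ArmTotals:
        """Sum the count matrix over all hut-nights of one arm.

        ``dead`` counts mosquitoes killed in any location; ``exited``
        counts veranda + window-trap cells.  An arm absent from the
        dataset is an error, except on an empty dataset where all
        totals are zero by convention.
        """
        sub = self.frame[self.frame["arm"] == arm]
        if sub.empty and len(self.frame) > 0:
            raise KeyError(f"arm {arm!r} not present in dataset")
        counts = sub[list(COUNT_COLUMNS)].to_numpy(dtype=np.int64)
        cube = counts.reshape(-1, 3, 2, 2)
        return ArmTotals(
            arm=arm,
            caught=int(cube.sum()),
            exited=int(cube[:, 1:].sum()),
            fed=int(cube[:, :, 1, :].sum()),
            dead=int(cube[:, :, :, 1].sum()),
            nights=int(sub["night"].nunique()),
        )

    def all_arm_totals(self) -> dict[str, ArmTotals]:
        return {arm: self.arm_totals(arm) for arm in self.arms}

    # -- design checks -----------------------------------------------

    def check_latin_square(self, period_length: int = 7) -> list[str]:
        """Verify the arm-rotation balance and return violation messages.

        Within one rotation period each hut holds a single arm and each
        arm sits in exactly one hut; across each complete block of
        ``n_arms`` periods every (hut, arm) pair occurs exactly once.
        An empty list means the recorded design is Latin-balanced.
        """
        violations: list[str] = []
        frame = self.frame
        if frame.empty:
            return violations
        period = (frame["night"] - 1) // period_length
        n_arms = frame["arm"].nunique()

        per_hut = frame.assign(period=period).groupby(["period", "hut"])["arm"].nunique()
        for (p, hut), n in per_hut.items():
            if n > 1:
                violations.append(f"period {p}: hut {hut!r} holds {n} different arms")
        per_arm = frame.assign(period=period).groupby(["period", "arm"])["hut"].nunique()
        for (p, arm), n in per_arm.items():
            if n > 1:
                violations.append(f"period {p}: arm {arm!r} occupies {n} huts")

        assignment = (
            frame.assign(period=period)
            .groupby(["period", "hut"])["arm"]
            .first()
            .reset_index()
        )
        n_periods = int(assignment["period"].max()) + 1
        for block_start in range(0, n_periods - n_arms + 1, n_arms):
            block = assignment[
                (assignment["period"] >= block_start)
                & (assignment["period"] < block_start + n_arms)
            ]
            counts = block.groupby(["hut", "arm"]).size()
            for (hut, arm), n in counts.items():
                if n > 1:
                    violations.append(
                        f"rotation block starting period {block_start}: "
                        f"arm {arm!r} appears {n} times in hut {hut!r}"
                    )
        return violations

    # -- I/O ----------------------------------------------------------

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.frame.to_csv(fh, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"records": self.frame.to_dict(orient="records")}, indent=1, default=int
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def read_trial_csv(path: str | Path, allowed_arms: Sequence[str] | None = None) -> TrialDataset:
    """Read and validate a trial CSV.

    The header must name the four metadata columns plus the 12 count
    columns of :data:`COUNT_COLUMNS`.  Lines starting with ``#`` are
    treated as comments (generated files carry a config stamp there).
    Integer coercion is strict; the first invalid row is reported by
    number.
    """
    try:
        frame = pd.read_csv(path, comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise TrialValidationError(f"{path}: empty or comment-only file") from exc
    return TrialDataset(frame, allowed_arms=allowed_arms)
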