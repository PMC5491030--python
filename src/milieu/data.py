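"""Participant-level dataset schema, standardization and predictor blocks.

A :class:`RawDataset` holds, per participant, baseline and follow-up two-week
frequency counts for every behavior, four cognition scores (intention,
attitude, subjective norm, perceived behavioral control) per behavior on 1-7
scales, and five personality scale scores.

:func:`standardize` z-scores every variable, multiplies the risk-behavior
count columns by -1 so that all items point toward healthier behavior, and
builds the analysis target: the *health behavior index*, the mean of the five
reversed follow-up health z-scores.

:func:`assemble_blocks` groups the standardized predictors into the five
blocks used by the prediction waves: health cognitions, personality,
lifestyle cognitions, ongoing lifestyle activities, baseline health behaviors.
The five follow-up health columns form the target only and belong to no block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import BehaviorCatalog, default_catalog

COGNITION_CONSTRUCTS = ("intention", "attitude", "norm", "pbc")
PERSONALITY_SCALES = ("locus", "acs_preocc", "acs_hesit", "esteem", "self_eff")

BLOCK_NAMES = (
    "health_cognitions",
    "personality",
    "lifestyle_cognitions",
    "lifestyle_activities",
    "baseline_health",
)


class SchemaError(ValueError):
    """CSV columns do not match the documented schema."""


class ValidationError(ValueError):
    """Values violate the schema's range/type constraints."""


class ZeroVarianceError(ValueError):
    """A column cannot be z-scored because it is constant."""


def cognition_column(behavior: str, construct: str) -> str:
    return f"cog_{behavior}_{construct}"


def expected_columns(catalog: BehaviorCatalog) -> list[str]:
    """Full ordered CSV column list for a catalog."""
    cols = ["pid"]
    cols += [f"beh_{n}_t1" for n in catalog.names]
    for n in catalog.names:
        cols += [cognition_column(n, c) for c in COGNITION_CONSTRUCTS]
    cols += [f"pers_{s}" for s in PERSONALITY_SCALES]
    cols += [f"beh_{n}_t2" for n in catalog.names]
    return cols


@dataclass
class RawDataset:
    """Validated participant-level data, one row per participant.

    ``baseline_counts`` / ``followup_counts`` columns are behavior names;
    ``cognitions`` columns are ``<behavior>_<construct>``; ``personality``
    columns are the five scale keys.
    """

    participant_ids: np.ndarray
    baseline_counts: pd.DataFrame
    cognitions: pd.DataFrame
    personality: pd.DataFrame
    followup_counts: pd.DataFrame

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    def validate(self, catalog: BehaviorCatalog) -> "RawDataset":
        n = self.n_participants
        for name, frame in (
            ("baseline_counts", self.baseline_counts),
            ("cognitions", self.cognitions),
            ("personality", self.personality),
            ("followup_counts", self.followup_counts),
        ):
            if len(frame) != n:
                raise ValidationError(f"{name} has {len(frame)} rows, expected {n}")
            if frame.isna().any().any():
                bad = frame.columns[frame.isna().any()].tolist()
                raise ValidationError(f"missing values in {name} columns {bad}")
        for name, frame in (("baseline_counts", self.baseline_counts), ("followup_counts", self.followup_counts)):
            arr = frame.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                col = frame.columns[np.where(~np.all(np.isclose(arr, np.round(arr)), axis=0))[0][0]]
                raise ValidationError(f"non-integer count in {name} column {col!r}")
            if (arr < 0).any():
                col = frame.columns[np.where((arr < 0).any(axis=0))[0][0]]
                raise ValidationError(f"negative count in {name} column {col!r}")
        cog = self.cognitions.to_numpy()
        if ((cog < 1) | (cog > 7)).any():
            rows = np.where(((cog < 1) | (cog > 7)).any(axis=1))[0]
            raise ValidationError(f"cognition score outside [1, 7] at row index {int(rows[0])}")
        return self

    # -- CSV round trip ------------------------------------------------
    def to_frame(self, catalog: BehaviorCatalog) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"pid": self.participant_ids}
        for n in catalog.names:
            cols[f"beh_{n}_t1"] = self.baseline_counts[n].to_numpy()
        for n in catalog.names:
            for c in COGNITION_CONSTRUCTS:
                cols[cognition_column(n, c)] = self.cognitions[f"{n}_{c}"].to_numpy()
        for s in PERSONALITY_SCALES:
            cols[f"pers_{s}"] = self.personality[s].to_numpy()
        for n in catalog.names:
            cols[f"beh_{n}_t2"] = self.followup_counts[n].to_numpy()
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path, catalog: BehaviorCatalog | None = None) -> None:
        catalog = catalog or default_catalog()
        # full repr precision so write -> read round-trips exactly
        self.to_frame(catalog).to_csv(path, index=False)


def load_raw(path: str | Path, catalog: BehaviorCatalog | None = None) -> RawDataset:
    """Read and validate a participant CSV following the documented schema."""
    catalog = catalog or default_catalog()
    frame = pd.read_csv(path)
    expected = expected_columns(catalog)
    missing = [c for c in expected if c not in frame.columns]
    extra = [c for c in frame.columns if c not in expected]
    if missing or extra:
        raise SchemaError(f"schema mismatch: missing columns {missing}, unexpected columns {extra}")
    raw = RawDataset(
        participant_ids=frame["pid"].to_numpy(),
        baseline_counts=pd.DataFrame({n: frame[f"beh_{n}_t1"].to_numpy() for n in catalog.names}),
        cognitions=pd.DataFrame(
            {
                f"{n}_{c}": frame[cognition_column(n, c)].to_numpy(dtype=float)
                for n in catalog.names
                for c in COGNITION_CONSTRUCTS
            }
        ),
        personality=pd.DataFrame({s: frame[f"pers_{s}"].to_numpy(dtype=float) for s in PERSONALITY_SCALES}),
        followup_counts=pd.DataFrame({n: frame[f"beh_{n}_t2"].to_numpy() for n in catalog.names}),
    )
    return raw.validate(catalog)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


@dataclass
class StandardizedDataset:
    """Column-wise z-scored dataset with risk reversal applied.

    Risk-behavior count columns (baseline and follow-up) are multiplied by -1
    after z-scoring; cognition columns are left unreversed by default (the
    questionnaire wording already targets the behavior as phrased), switchable
    via ``reverse_cognitions``.  ``health_index`` is the row mean of the five
    reversed follow-up health z-scores and is the analysis target throughout.
    """

    z_baseline: pd.DataFrame
    z_cognitions: pd.DataFrame
    z_personality: pd.DataFrame
    z_followup: pd.DataFrame
    health_index: pd.Series
    reverse_cognitions: bool = False

    @property
    def n_participants(self) -> int:
        return len(self.health_index)


def _zscore_frame(frame: pd.DataFrame, label: str) -> pd.DataFrame:
    arr = frame.to_numpy(dtype=float)
    sd = arr.std(axis=0, ddof=1)
    if (sd == 0).any():
        col = frame.columns[int(np.where(sd == 0)[0][0])]
        raise ZeroVarianceError(f"zero-variance column {col!r} in {label}; cannot z-score")
    z = (arr - arr.mean(axis=0)) / sd
    return pd.DataFrame(z, columns=frame.columns)


def standardize(
    raw: RawDataset,
    catalog: BehaviorCatalog | None = None,
    reverse_cognitions: bool = False,
) -> StandardizedDataset:
    """Z-score (sample SD, n-1) every column, reverse risk items, build the index."""
    catalog = catalog or default_catalog()
    z_base = _zscore_frame(raw.baseline_counts, "baseline_counts")
    z_cog = _zscore_frame(raw.cognitions, "cognitions")
    z_pers = _zscore_frame(raw.personality, "personality")
    z_follow = _zscore_frame(raw.followup_counts, "followup_counts")
    for name in catalog.risk_names:
        z_base[name] = -z_base[name]
        z_follow[name] = -z_follow[name]
        if reverse_cognitions:
            for c in COGNITION_CONSTRUCTS:
                z_cog[f"{name}_{c}"] = -z_cog[f"{name}_{c}"]
    index = z_follow[list(catalog.health_names)].mean(axis=1)
    index.name = "health_index"
    return StandardizedDataset(z_base, z_cog, z_pers, z_follow, index, reverse_cognitions)


# ---------------------------------------------------------------------------
# predictor blocks
# ---------------------------------------------------------------------------


@dataclass
class PredictorBlocks:
    """The five disjoint predictor blocks over a standardized dataset.

    Each block is a DataFrame with globally unique, prefixed column names so
    concatenation (the saturated design) is unambiguous.  Follow-up health
    columns never appear: they form the target only.
    """

    blocks: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.blocks)

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(f.shape[1] for f in self.blocks.values())

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.blocks[name]

    def saturated(self) -> pd.DataFrame:
        """All predictor columns concatenated in block order."""
        return pd.concat(list(self.blocks.values()), axis=1)


def assemble_blocks(std: StandardizedDataset, catalog: BehaviorCatalog | None = None) -> PredictorBlocks:
    catalog = catalog or default_catalog()
    health = list(catalog.health_names)
    lifestyle = list(catalog.lifestyle_names)

    def cog_frame(names: list[str]) -> pd.DataFrame:
        cols = [f"{n}_{c}" for n in names for c in COGNITION_CONSTRUCTS]
        out = std.z_cognitions[cols].copy()
        out.columns = [f"cog_{c}" for c in cols]
        return out

    personality = std.z_personality.copy()
    personality.columns = [f"pers_{s}" for s in personality.columns]
    activities = std.z_followup[lifestyle].copy()
    activities.columns = [f"act_{n}" for n in lifestyle]
    baseline = std.z_baseline[health].copy()
    baseline.columns = [f"base_{n}" for n in health]

    return PredictorBlocks(
        {
            "health_cognitions": cog_frame(health),
            "personality": personality,
            "lifestyle_cognitions": cog_frame(lifestyle),
            "lifestyle_activities": activities,
            "baseline_health": baseline,
        }
    )
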