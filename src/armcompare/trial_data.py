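"""Trial/arm data model, CSV ingestion and validation, and composable filters.

The unit of analysis is the *arm* of a randomized controlled trial of
medication or psychotherapy for youth depression, summarized by its
baseline and endpoint statistics on a named depression scale.  A
:class:`TrialDatabase` bundles study-level records (modality, sites,
sample characteristics), arm-level records (role, control type, summary
statistics, intervention-intensity descriptors), and a registry of scale
definitions used to normalize severity across instruments.

Missing values are empty CSV cells and travel as NaN; no sentinel numbers
are used anywhere.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DuplicateError,
    ScaleLookupError,
    SchemaError,
)

MODALITIES = ("medication", "psychotherapy")
ROLES = ("active", "control")
CONTROL_TYPES = ("pill_placebo", "waitlist", "tau", "other", "none")

ARM_COLUMNS = [
    "study_id", "arm_id", "role", "control_type", "n", "scale",
    "baseline_mean", "baseline_sd", "post_mean", "post_sd",
    "change_mean", "change_sd", "ci_low", "ci_high",
    "se_reported", "t_reported", "p_reported",
    "n_sessions", "session_minutes", "sessions_per_week",
    "total_weeks", "total_hours",
]
STUDY_COLUMNS = [
    "study_id", "modality", "n_sites", "subclinical",
    "percent_female", "mean_age", "sd_age", "n_total",
]
SCALE_COLUMNS = ["name", "min_score", "max_score"]

#: Reference pre-post correlation used wherever a single deterministic
#: correlation value is needed (midpoint of the simulated 0.45-0.9 range).
REFERENCE_R = 0.675


@dataclass(frozen=True)
class ScaleSpec:
    """A depression rating scale with its total-score bounds."""

    name: str
    min_score: float
    max_score: float

    def __post_init__(self) -> None:
        if not self.max_score > self.min_score:
            raise SchemaError(
                f"scale {self.name!r}: max_score ({self.max_score}) must "
                f"exceed min_score ({self.min_score})"
            )

    @property
    def range(self) -> float:
        return self.max_score - self.min_score


#: Built-in scales.  CDRS-R bounds are the instrument's published total
#: score span; the HAM-D span is the package's documented convention.
CDRS_R = ScaleSpec("CDRS-R", 17.0, 113.0)
HAM_D = ScaleSpec("HAM-D", 0.0, 52.0)
BUILTIN_SCALES = {s.name: s for s in (CDRS_R, HAM_D)}


@dataclass(frozen=True)
class FilterSpec:
    """Conjunction of sensitivity-analysis exclusion criteria.

    ``max_effect_variance`` is evaluated against each arm's pre-post SMD
    sampling variance computed at the reference correlation
    ``r = 0.675`` (strict inequality), which makes the filter
    deterministic even though the variance depends on r.
    """

    exclude_waitlist: bool = False
    exclude_subclinical: bool = False
    scale_in: frozenset[str] | None = None
    max_effect_variance: float | None = None
    require_post_sd: bool = False
    all_female_excluded: bool = False

    @classmethod
    def from_dict(cls, criteria: Mapping) -> "FilterSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(criteria) - known
        if unknown:
            raise ConfigError(f"unknown filter criteria: {sorted(unknown)}")
        crit = dict(criteria)
        if crit.get("scale_in") is not None:
            crit["scale_in"] = frozenset(crit["scale_in"])
        return cls(**crit)


class TrialDatabase:
    """Validated collection of study- and arm-level summary records.

    Parameters
    ----------
    studies, arms : pandas.DataFrame
        Tables with the canonical column sets (see ``STUDY_COLUMNS`` and
        ``ARM_COLUMNS``).  Extra columns are rejected as schema errors.
    scales : mapping of str to ScaleSpec
        Registry resolving every arm's ``scale`` field.
    """

    def __init__(
        self,
        studies: pd.DataFrame,
        arms: pd.DataFrame,
        scales: Mapping[str, ScaleSpec] | None = None,
        waitlist_only_studies: frozenset[str] | None = None,
    ) -> None:
        self.studies = studies.reset_index(drop=True).copy()
        self.arms = arms.reset_index(drop=True).copy()
        self.scales = dict(scales) if scales is not None else dict(BUILTIN_SCALES)
        self.report: dict = {}
        self._validate()
        # derived once from the full arm set and carried through subsets,
        # so sensitivity filters stay order-independent
        if waitlist_only_studies is None:
            is_ctl = self.arms["role"] == "control"
            is_wl = self.arms["control_type"] == "waitlist"
            by_study = is_wl.groupby(self.arms["study_id"]).sum()
            ctl_by_study = is_ctl.groupby(self.arms["study_id"]).sum()
            waitlist_only_studies = frozenset(
                by_study.index[(by_study == ctl_by_study) & (ctl_by_study > 0)]
            )
        self.waitlist_only_studies = waitlist_only_studies

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        studies, arms = self.studies, self.arms
        for col in STUDY_COLUMNS:
            if col not in studies.columns:
                studies[col] = np.nan
        for col in ARM_COLUMNS:
            if col not in arms.columns:
                arms[col] = np.nan
        extra = [c for c in arms.columns if c not in ARM_COLUMNS]
        if extra:
            raise SchemaError(f"unexpected arm columns: {extra}")
        extra = [c for c in studies.columns if c not in STUDY_COLUMNS]
        if extra:
            raise SchemaError(f"unexpected study columns: {extra}")
        self.studies = studies = studies[STUDY_COLUMNS]
        self.arms = arms = arms[ARM_COLUMNS]

        dup = studies["study_id"][studies["study_id"].duplicated()]
        if len(dup):
            raise DuplicateError(f"duplicate study_id: {sorted(set(dup))}")
        dup = arms[["study_id", "arm_id"]][
            arms[["study_id", "arm_id"]].duplicated()
        ]
        if len(dup):
            raise DuplicateError(
                f"duplicate (study_id, arm_id): {dup.values.tolist()}"
            )

        bad = studies.loc[~studies["modality"].isin(MODALITIES), "study_id"]
        if len(bad):
            raise SchemaError(f"unknown modality for studies {list(bad)}")
        bad = arms.loc[~arms["role"].isin(ROLES)]
        if len(bad):
            raise SchemaError(
                f"unknown role in rows {list(bad.index)}: "
                f"{sorted(set(bad['role']))}"
            )
        bad = arms.loc[~arms["control_type"].isin(CONTROL_TYPES)]
        if len(bad):
            raise SchemaError(
                f"unknown control_type in rows {list(bad.index)}: "
                f"{sorted(set(bad['control_type']))}"
            )

        orphans = set(arms["study_id"]) - set(studies["study_id"])
        if orphans:
            raise SchemaError(f"arms reference unknown studies: {sorted(orphans)}")
        unknown_scales = set(arms["scale"].dropna()) - set(self.scales)
        if unknown_scales:
            raise ScaleLookupError(
                f"arms reference unregistered scales: {sorted(unknown_scales)}"
            )

        active = arms["role"] == "active"
        if (active & (arms["control_type"] != "none")).any():
            raise SchemaError("active arms must have control_type 'none'")
        if ((~active) & (arms["control_type"] == "none")).any():
            raise SchemaError("control arms must have a control_type")
        modality = arms["study_id"].map(
            studies.set_index("study_id")["modality"]
        )
        bad_pp = (arms["control_type"] == "pill_placebo") & (
            modality != "medication"
        )
        if bad_pp.any():
            raise SchemaError(
                "pill_placebo control in non-medication studies: "
                f"{sorted(set(arms.loc[bad_pp, 'study_id']))}"
            )

        sd = arms["baseline_sd"]
        if ((sd <= 0) & sd.notna()).any():
            raise SchemaError("baseline_sd must be > 0 where present")
        if (arms["n"].dropna() <= 0).any():
            raise SchemaError("arm n must be a positive integer")
        no_effect = arms["post_mean"].isna() & arms["change_mean"].isna()
        if no_effect.any():
            raise SchemaError(
                "arms with neither post_mean nor change_mean: "
                f"{arms.loc[no_effect, ['study_id', 'arm_id']].values.tolist()}"
            )
        ns = studies["n_sites"].dropna()
        if (ns < 1).any():
            raise SchemaError("n_sites must be >= 1 where present")
        pf = studies["percent_female"].dropna()
        if ((pf < 0) | (pf > 100)).any():
            raise SchemaError("percent_female must lie in [0, 100]")

        counts = arms.groupby("study_id").size()
        partial = [
            sid for sid in studies["study_id"] if counts.get(sid, 0) < 2
        ]
        if partial:
            warnings.warn(
                f"studies with < 2 extracted arms (partial extraction): "
                f"{partial}",
                stacklevel=3,
            )
        self.report = self._build_report(partial)

    def _build_report(self, partial: list[str]) -> dict:
        modality = self.arms["study_id"].map(
            self.studies.set_index("study_id")["modality"]
        )
        miss = {
            c: int(self.arms[c].isna().sum())
            for c in ("post_sd", "change_sd", "n_sessions", "total_hours")
        }
        miss["n_sites"] = int(self.studies["n_sites"].isna().sum())
        return {
            "n_studies": {
                m: int((self.studies["modality"] == m).sum())
                for m in MODALITIES
            },
            "n_arms": {
                f"{m}_{r}": int(
                    ((modality == m) & (self.arms["role"] == r)).sum()
                )
                for m in MODALITIES
                for r in ROLES
            },
            "missing": miss,
            "partial_studies": partial,
        }

    # -- convenience --------------------------------------------------

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    def arms_with_modality(self) -> pd.DataFrame:
        """Arms joined with their study's modality and subclinical flag."""
        study_cols = self.studies.set_index("study_id")[
            ["modality", "subclinical", "n_sites"]
        ]
        out = self.arms.join(study_cols, on="study_id")
        out["arm_type"] = out["modality"].str.cat(out["role"], sep="_")
        return out

    def scale_of(self, name: str) -> ScaleSpec:
        try:
            return self.scales[name]
        except KeyError:
            raise ScaleLookupError(f"unregistered scale: {name!r}") from None

    # -- persistence ---------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write arms.csv, studies.csv, scales.csv with empty cells for NaN."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.arms.to_csv(directory / "arms.csv", index=False)
        self.studies.to_csv(directory / "studies.csv", index=False)
        pd.DataFrame(
            [
                {"name": s.name, "min_score": s.min_score, "max_score": s.max_score}
                for s in self.scales.values()
            ],
            columns=SCALE_COLUMNS,
        ).to_csv(directory / "scales.csv", index=False)

    def subset(self, keep_arms: pd.Series) -> "TrialDatabase":
        """New database restricted to arms where ``keep_arms`` is True;
        studies left with no arms are dropped."""
        arms = self.arms[keep_arms.to_numpy(dtype=bool)]
        studies = self.studies[
            self.studies["study_id"].isin(arms["study_id"])
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return TrialDatabase(
                studies, arms, self.scales,
                waitlist_only_studies=self.waitlist_only_studies,
            )


def _read_csv(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"study_id": str, "arm_id": str},
                     float_precision="round_trip")
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


def load_scales(path: str | Path) -> dict[str, ScaleSpec]:
    df = _read_csv(path, SCALE_COLUMNS)
    return {
        row["name"]: ScaleSpec(row["name"], float(row["min_score"]),
                               float(row["max_score"]))
        for _, row in df.iterrows()
    }


def load_trials(
    path: str | Path,
    studies_path: str | Path | None = None,
    scales_path: str | Path | None = None,
) -> TrialDatabase:
    """Load a validated :class:`TrialDatabase` from CSV files.

    ``path`` may be a directory containing ``arms.csv``, ``studies.csv``
    and ``scales.csv``, or the arms CSV itself with the two companion
    paths given explicitly.  An arms file with zero rows yields an empty
    database with a warning.
    """
    path = Path(path)
    if path.is_dir():
        arms_path = path / "arms.csv"
        studies_path = studies_path or path / "studies.csv"
        scales_path = scales_path or path / "scales.csv"
    else:
        arms_path = path
        if studies_path is None:
            raise ConfigError("studies_path required when loading from a file")
    arms = _read_csv(arms_path, ["study_id", "arm_id", "role"])
    studies = _read_csv(studies_path, ["study_id", "modality"])
    scales = (
        load_scales(scales_path)
        if scales_path is not None and Path(scales_path).exists()
        else dict(BUILTIN_SCALES)
    )
    if "subclinical" in studies.columns:
        studies["subclinical"] = (
            studies["subclinical"]
            .map({True: True, False: False, "True": True, "False": False,
                  1: True, 0: False, "1": True, "0": False})
            .fillna(False)
            .astype(bool)
        )
    if len(arms) == 0:
        warnings.warn("empty arms table: database has no studies")
    return TrialDatabase(studies, arms, scales)


def apply_filter(db: TrialDatabase, criteria: FilterSpec | Mapping) -> TrialDatabase:
    """Return a new database satisfying every criterion in ``criteria``.

    Waitlist exclusion removes whole studies whose control arms are all
    waitlist; a multi-control study with a non-waitlist control is
    retained with its waitlist arm(s) dropped.  The variance criterion is
    arm-level and strict (< threshold) at the reference correlation.
    """
    if not isinstance(criteria, FilterSpec):
        criteria = FilterSpec.from_dict(criteria)
    arms = db.arms
    studies = db.studies.set_index("study_id")
    keep = pd.Series(True, index=arms.index)

    if criteria.exclude_waitlist:
        keep &= ~arms["study_id"].isin(db.waitlist_only_studies)
        keep &= ~(arms["control_type"] == "waitlist")

    if criteria.exclude_subclinical:
        sub = arms["study_id"].map(studies["subclinical"]).fillna(False)
        keep &= ~sub.astype(bool)

    if criteria.all_female_excluded:
        pf = arms["study_id"].map(studies["percent_female"])
        keep &= ~(pf >= 100.0).fillna(False)

    if criteria.scale_in is not None:
        keep &= arms["scale"].isin(criteria.scale_in)

    if criteria.require_post_sd:
        keep &= arms["post_sd"].notna()

    if criteria.max_effect_variance is not None:
        from .effect_size import compute_effects  # deferred: avoids cycle

        eff = compute_effects(db, r=REFERENCE_R)
        var = eff.set_index(["study_id", "arm_id"])["variance"]
        arm_var = pd.MultiIndex.from_frame(arms[["study_id", "arm_id"]]).map(var)
        keep &= pd.Series(arm_var, index=arms.index) < criteria.max_effect_variance

    return db.subset(keep)
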