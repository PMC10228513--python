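"""Trial data container and wide-CSV I/O.

A trial is stored in wide form, one row per patient:

``id, L0[_j], A0, L1[_j], A1[, L2[_j], A2], Y[, cf_Y_0, cf_Y_1]``

* ``A0`` is the randomized arm (0/1), ``A1`` (and ``A2`` for two-timepoint
  designs) are cumulative intercurrent-event (ICE) indicators: ``A_k = 1``
  means the ICE has occurred by timepoint *k*, so the pattern is absorbing
  (``A1 = 1`` forces ``A2 = 1``).
* Covariate blocks ``L0``, ``L1``, ``L2`` may be a single column (``L1``) or a
  suffixed set (``L1_1, L1_2, ...``).
* ``Y`` is the continuous final outcome; it (and ``L2``) may be missing after
  an ICE.  Missing cells are empty in the CSV (optionally the literal ``NA``).
* ``cf_Y_0``/``cf_Y_1`` are counterfactual outcomes under the no-ICE regime of
  each arm.  They exist only for simulated data and are stripped by
  :meth:`TrialDataset.analysis_frame`, the only view estimators ever read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

CF_COLS = ("cf_Y_0", "cf_Y_1")


def _block_cols(columns, prefix: str) -> list[str]:
    """Columns forming a covariate block: exact ``prefix`` or ``prefix_<j>``."""
    pat = re.compile(rf"^{prefix}(_\d+)?$")
    return [c for c in columns if pat.match(c)]


@dataclass(frozen=True)
class EstimandSpec:
    """The hypothetical no-ICE estimand.

    ``regime`` is the static regime vector (a0, 0, ..., 0) of length K+1; all
    post-baseline entries must be 0 because this package targets only the
    strategy in which the ICE is prevented.  ``contrast`` selects the arm
    difference E(Y^{1,0,...}) - E(Y^{0,0,...}) instead of a single arm mean.
    """

    regime: tuple[int, ...] = (1, 0)
    contrast: bool = False

    def __post_init__(self):
        if self.regime[0] not in (0, 1):
            raise ValidationError("regime arm entry must be 0 or 1")
        if any(a != 0 for a in self.regime[1:]):
            raise ValidationError(
                "only the no-ICE hypothetical regime is supported: "
                "post-baseline regime entries must all be 0"
            )

    @property
    def arm(self) -> int:
        return int(self.regime[0])


class TrialDataset:
    """Wide-format trial data with structural validation.

    Parameters
    ----------
    df:
        One row per patient with the documented columns.
    k_ice_times:
        Number of ICE timepoints K (1 or 2).
    validate:
        Run structural checks (binary indicators, absorbing ICE pattern).
    """

    def __init__(self, df: pd.DataFrame, k_ice_times: int, validate: bool = True):
        if k_ice_times not in (1, 2):
            raise ValidationError(f"k_ice_times must be 1 or 2, got {k_ice_times}")
        self.k = int(k_ice_times)
        self.df = df.reset_index(drop=True)
        if validate:
            self.validate()

    # -- column layout ------------------------------------------------------
    @property
    def l0_cols(self) -> list[str]:
        return _block_cols(self.df.columns, "L0")

    @property
    def l1_cols(self) -> list[str]:
        return _block_cols(self.df.columns, "L1")

    @property
    def l2_cols(self) -> list[str]:
        return _block_cols(self.df.columns, "L2") if self.k == 2 else []

    @property
    def ice_cols(self) -> list[str]:
        return ["A1", "A2"][: self.k]

    @property
    def has_counterfactuals(self) -> bool:
        return all(c in self.df.columns for c in CF_COLS)

    @property
    def n(self) -> int:
        return len(self.df)

    # -- views --------------------------------------------------------------
    def analysis_frame(self) -> pd.DataFrame:
        """The factual data estimators are allowed to see.

        Counterfactual columns are dropped so no estimator can touch them even
        by accident.
        """
        return self.df.drop(columns=[c for c in CF_COLS if c in self.df.columns])

    def counterfactual(self, arm: int) -> pd.Series:
        if not self.has_counterfactuals:
            raise ValidationError("dataset carries no counterfactual columns")
        return self.df[f"cf_Y_{int(arm)}"]

    def ice_free(self) -> pd.Series:
        """Boolean mask: no ICE through the final timepoint."""
        mask = self.df["A1"] == 0
        if self.k == 2:
            mask &= self.df["A2"] == 0
        return mask

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        cols = self.df.columns
        required = ["id", "A0", "A1", "Y"] if self.k == 1 else ["id", "A0", "A1", "A2", "Y"]
        for c in required:
            if c not in cols:
                raise FormatError(f"missing mandatory column: {c}")
        if not self.l0_cols:
            raise FormatError("missing mandatory column: L0")
        if not self.l1_cols:
            raise FormatError("missing mandatory column: L1")
        if self.k == 2 and not self.l2_cols:
            raise FormatError("missing mandatory column: L2")

        for c in ["A0", *self.ice_cols]:
            vals = self.df[c]
            if vals.isna().any():
                raise ValidationError(f"column {c} contains missing values")
            arr = vals.to_numpy()
            if not np.isin(arr, [0, 1]).all():
                raise ValidationError(f"column {c} is not binary (values outside {{0, 1}})")

        if self.k == 2:
            bad = self.df.loc[(self.df["A1"] == 1) & (self.df["A2"] == 0), "id"].tolist()
            if bad:
                raise ValidationError(
                    "non-absorbing ICE pattern (A1=1 but A2=0) for patients: "
                    + ", ".join(map(str, bad))
                )

        if self.df["id"].duplicated().any():
            dup = self.df.loc[self.df["id"].duplicated(), "id"].tolist()
            raise ValidationError("duplicate patient ids: " + ", ".join(map(str, dup)))

    # -- conveniences -------------------------------------------------------
    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TrialDataset(n={self.n}, K={self.k}, "
            f"counterfactuals={self.has_counterfactuals})"
        )


def load_trial_csv(
    path: str | Path,
    k_ice_times: int,
    accept_na_strings: bool = False,
) -> TrialDataset:
    """Read a wide-format trial CSV.

    Missing values are empty cells; with ``accept_na_strings`` the literal
    string ``NA`` is also treated as missing.
    """
    na_values = ["", "NA"] if accept_na_strings else [""]
    df = pd.read_csv(
        path, keep_default_na=False, na_values=na_values, float_precision="round_trip"
    )
    for c in df.columns:
        if c != "id":
            try:
                df[c] = pd.to_numeric(df[c])
            except (ValueError, TypeError) as exc:
                raise FormatError(f"column {c} is not numeric: {exc}") from exc
    return TrialDataset(df, k_ice_times=k_ice_times)


def write_trial_csv(
    data: TrialDataset,
    path: str | Path,
    drop_post_ice: bool = False,
    include_counterfactuals: bool = False,
) -> Path:
    """Write a trial dataset to wide CSV.

    With ``drop_post_ice`` every value recorded after a patient's first ICE is
    blanked: ``Y`` for anyone with an ICE at any timepoint, and ``L2`` for
    patients whose ICE occurred at timepoint 1.  This reproduces the common
    missing-data preprocessing step of deleting post-ICE measurements.
    Counterfactual columns are never written unless explicitly requested.
    """
    df = data.df.copy()
    if drop_post_ice:
        any_ice = ~data.ice_free()
        df.loc[any_ice, "Y"] = np.nan
        if data.k == 2:
            df.loc[df["A1"] == 1, data.l2_cols] = np.nan
    if not include_counterfactuals:
        df = df.drop(columns=[c for c in CF_COLS if c in df.columns])
    path = Path(path)
    df.to_csv(path, index=False)
    return path
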