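"""Delimited-text readers/writers and the RAND HIE analysis schema.

Files are comma-separated with a mandatory header row, UTF-8, '.' decimal.
Costs are stored as given -- no log transform or winsorizing on input; the
models handle scale through their links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulation import CostDataset

log = logging.getLogger("tweediecost")

__all__ = ["load_cost_table", "write_cost_table", "RandHieSchema", "RAND_HIE"]


@dataclass(frozen=True)
class RandHieSchema:
    """Column schema of the RAND Health Insurance Experiment cost extract.

    Outcome: total annual cost in dollars (outpatient, drug, supply,
    psychotherapy and inpatient expenses).  The thirteen covariates are the
    socio-economic and insurance-plan variables conventionally used to model
    utilization; ``idp``, ``female``, ``black`` and ``hlthg`` are 0/1
    dummies.
    """

    outcome: str = "cost"
    covariates: tuple = (
        "age",       # years
        "disea",     # number of chronic diseases
        "physlm",    # number of physical limitations
        "logc",      # log(coinsurance rate + 1)
        "idp",       # individual deductible plan (0/1)
        "lpi",       # log participation incentive payment
        "fmde",      # maximum expenditure function
        "linc",      # log family income
        "lfam",      # log family size
        "female",    # 0/1
        "black",     # 0/1
        "educdec",   # education of household head, years
        "hlthg",     # self-rated good health (0/1)
    )
    dummies: tuple = ("idp", "female", "black", "hlthg")

    def match_columns(self, columns) -> dict:
        """Case-insensitive mapping from schema names to file columns."""
        lower = {str(c).lower(): str(c) for c in columns}
        mapping = {}
        missing = []
        for name in (self.outcome, *self.covariates):
            if name.lower() in lower:
                mapping[name] = lower[name.lower()]
            else:
                missing.append(name)
        if missing:
            raise ValueError(f"missing RAND HIE columns: {missing}")
        return mapping

    def validate(self, df: pd.DataFrame) -> dict:
        mapping = self.match_columns(df.columns)
        sub = df[[mapping[c] for c in (self.outcome, *self.covariates)]]
        arr = sub.to_numpy(dtype=float)
        if np.any(arr[:, 0] < 0):
            raise ValueError("negative total cost in RAND HIE extract")
        for d in self.dummies:
            col = df[mapping[d]].to_numpy(dtype=float)
            if not np.all(np.isin(col, (0.0, 1.0))):
                raise ValueError(f"dummy column {d!r} has values outside {{0, 1}}")
        zero_frac = float(np.mean(arr[:, 0] == 0))
        log.info(
            "RAND HIE extract validated: n=%d, zero fraction=%.4f (mapping %s)",
            len(df), zero_frac, mapping,
        )
        return {"n": len(df), "zero_fraction": zero_frac, "mapping": mapping}


RAND_HIE = RandHieSchema()


def load_cost_table(path, outcome_col: str = "y", covariate_cols=None) -> CostDataset:
    """Read a delimited cost table into a :class:`CostDataset`.

    Rows containing any missing value are dropped (counted in the log).
    Raises on missing columns or negative costs (naming the first bad row).
    """
    df = pd.read_csv(path)
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns if c != outcome_col]
    missing = [c for c in [outcome_col, *covariate_cols] if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")
    sub = df[[*covariate_cols, outcome_col]].apply(pd.to_numeric, errors="coerce")
    n_dropped = int(sub.isna().any(axis=1).sum())
    if n_dropped:
        log.info("dropped %d rows with missing values from %s", n_dropped, path)
        sub = sub.dropna()
    y = sub[outcome_col].to_numpy(dtype=float)
    neg = np.flatnonzero(y < 0)
    if neg.size:
        raise ValueError(f"negative cost at data row {int(neg[0]) + 1} of {path}")
    return CostDataset(
        X=sub[covariate_cols].to_numpy(dtype=float),
        y=y,
        colnames=[str(c) for c in covariate_cols],
    )


def write_cost_table(data: CostDataset, path) -> None:
    """Write a :class:`CostDataset` as CSV (header x1..xk, y)."""
    data.to_frame().to_csv(path, index=False)


def load_randhie(path) -> CostDataset:
    """Load and validate the RAND HIE cost extract against the schema."""
    df = pd.read_csv(path)
    info = RAND_HIE.validate(df)
    mapping = info["mapping"]
    return CostDataset(
        X=df[[mapping[c] for c in RAND_HIE.covariates]].to_numpy(dtype=float),
        y=df[mapping[RAND_HIE.outcome]].to_numpy(dtype=float),
        colnames=list(RAND_HIE.covariates),
    )
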