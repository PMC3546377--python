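"""Reading and writing meta-analytic data files.

Two input dialects are supported:

* **long format** — one row per (study, outcome) pair with columns
  ``study, outcome, estimate, variance`` plus optional study-level covariate
  columns; missing outcomes are simply absent rows.  Within-study
  correlations come from a :class:`WithinCorrSpec` (zero, a common value, or
  a per-study covariance file with columns
  ``study, outcome_a, outcome_b, cov``).
* **wide bivariate format** — one row per study with columns
  ``Y1, S11, Y2, S22, S12`` (an optional ``study`` column labels the rows),
  carrying the full 2x2 within-study covariance.

The bundled periodontal dataset (five trials comparing surgical and
non-surgical treatment on probing-depth and attachment-level improvement,
in mm) ships in the wide dialect and loads via :func:`load_periodontal`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .data_model import (
    HeterogeneityReport,
    MVDataset,
    OutcomeSpace,
    StudyRecord,
    ValidationError,
)

__all__ = [
    "WithinCorrSpec",
    "read_long",
    "write_long",
    "read_wide_berkey",
    "load_periodontal",
    "fit_to_dict",
    "write_report_json",
    "write_report_csv",
]


@dataclass(frozen=True)
class WithinCorrSpec:
    """How to fill the off-diagonal within-study covariances of long data."""

    mode: str  # "zero" | "common" | "file"
    value: float | None = None
    table: dict | None = None  # {(study, outcome_a, outcome_b): cov}

    @classmethod
    def zero(cls) -> "WithinCorrSpec":
        return cls(mode="zero")

    @classmethod
    def common(cls, value: float) -> "WithinCorrSpec":
        if not (-1.0 < value < 1.0):
            raise ValidationError("common within-study correlation must lie in (-1, 1)")
        return cls(mode="common", value=float(value))

    @classmethod
    def from_file(cls, path) -> "WithinCorrSpec":
        df = pd.read_csv(path)
        need = {"study", "outcome_a", "outcome_b", "cov"}
        if not need.issubset(df.columns):
            raise ValidationError(f"covariance file needs columns {sorted(need)}")
        table = {}
        for row in df.itertuples(index=False):
            key = (str(row.study), str(row.outcome_a), str(row.outcome_b))
            table[key] = float(row.cov)
            table[(key[0], key[2], key[1])] = float(row.cov)
        return cls(mode="file", table=table)

    def cov(self, study: str, out_a: str, out_b: str, var_a: float, var_b: float) -> float:
        if self.mode == "zero":
            return 0.0
        if self.mode == "common":
            return self.value * np.sqrt(var_a * var_b)
        return self.table.get((study, out_a, out_b), 0.0)


def read_long(
    path,
    corr: WithinCorrSpec | None = None,
    outcomes: list[str] | None = None,
) -> MVDataset:
    """Assemble a dataset from a long-format CSV.

    Outcome ordering is ``outcomes`` if given, else first appearance in the
    file.  Extra columns become study-level covariates (their value must be
    constant within a study).
    """
    corr = corr or WithinCorrSpec.zero()
    df = pd.read_csv(path)
    need = {"study", "outcome", "estimate", "variance"}
    if not need.issubset(df.columns):
        raise ValidationError(f"long format needs columns {sorted(need)}")
    df = df.copy()
    df["study"] = df["study"].astype(str)
    df["outcome"] = df["outcome"].astype(str)
    dup = df.duplicated(subset=["study", "outcome"])
    if dup.any():
        pair = df.loc[dup, ["study", "outcome"]].iloc[0]
        raise ValidationError(
            f"duplicate (study, outcome) pair: ({pair['study']}, {pair['outcome']})"
        )
    if (df["variance"] <= 0).any():
        bad = df.loc[df["variance"] <= 0, "study"].iloc[0]
        raise ValidationError(f"non-positive variance for study {bad!r}")
    if outcomes is None:
        outcomes = list(dict.fromkeys(df["outcome"]))
    space = OutcomeSpace(outcomes)
    extra_cols = [c for c in df.columns if c not in need]
    covariates: dict[str, dict[str, float]] = {}
    studies = []
    for sid in dict.fromkeys(df["study"]):
        sub = df[df["study"] == sid]
        sub = sub.set_index("outcome").loc[
            [o for o in outcomes if o in set(sub["outcome"])]
        ]
        obs = [space.index(o) for o in sub.index]
        var = sub["variance"].to_numpy(dtype=float)
        k = len(obs)
        S = np.diag(var)
        for a in range(k):
            for b in range(a + 1, k):
                S[a, b] = S[b, a] = corr.cov(
                    sid, sub.index[a], sub.index[b], var[a], var[b]
                )
        try:
            rec = StudyRecord(sid, obs, sub["estimate"].to_numpy(dtype=float), S)
        except ValidationError as exc:
            raise ValidationError(f"study {sid!r}: assembled S is invalid ({exc})") from exc
        studies.append(rec)
        if extra_cols:
            vals = {}
            for c in extra_cols:
                col = sub[c].dropna()
                if col.empty:
                    continue
                if col.nunique() > 1:
                    raise ValidationError(
                        f"covariate {c!r} varies within study {sid!r}; "
                        "covariates are study-level"
                    )
                vals[c] = float(col.iloc[0])
            covariates[sid] = vals
    return MVDataset(space, studies, covariates=covariates or None)


def write_long(d: MVDataset, path) -> None:
    """Serialise a dataset to the long CSV dialect (full precision).

    Off-diagonal within-study covariances are written alongside as the same
    file would be re-read with a ``file``-mode correlation spec; they go to
    ``<path>`` with suffix ``.cov.csv``.
    """
    rows = []
    cov_rows = []
    for rec in d.studies:
        for pos, j in enumerate(rec.observed):
            row = {
                "study": rec.study_id,
                "outcome": d.space.names[j],
                "estimate": rec.y[pos],
                "variance": rec.S[pos, pos],
            }
            if d.covariates and rec.study_id in d.covariates:
                row.update(d.covariates[rec.study_id])
            rows.append(row)
        for a in range(rec.k):
            for b in range(a + 1, rec.k):
                cov_rows.append(
                    {
                        "study": rec.study_id,
                        "outcome_a": d.space.names[rec.observed[a]],
                        "outcome_b": d.space.names[rec.observed[b]],
                        "cov": rec.S[a, b],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
    if cov_rows:
        pd.DataFrame(cov_rows).to_csv(str(path) + ".cov.csv", index=False)


def read_wide_berkey(path, outcome_names=("Y1", "Y2")) -> MVDataset:
    """Read the wide bivariate dialect (columns Y1, S11, Y2, S22, S12)."""
    df = pd.read_csv(path)
    need = {"Y1", "S11", "Y2", "S22", "S12"}
    if not need.issubset(df.columns):
        raise ValidationError(f"wide format needs columns {sorted(need)}")
    if df.empty:
        raise ValidationError("wide-format file contains no studies")
    space = OutcomeSpace(outcome_names)
    studies = []
    for i, row in enumerate(df.itertuples(index=False)):
        sid = str(getattr(row, "study", i + 1))
        S = np.array([[row.S11, row.S12], [row.S12, row.S22]], dtype=float)
        if row.S12**2 >= row.S11 * row.S22:
            raise ValidationError(
                f"study {sid!r}: S12^2 >= S11*S22, within-study covariance "
                "is not positive definite"
            )
        studies.append(StudyRecord(sid, (0, 1), [row.Y1, row.Y2], S))
    return MVDataset(space, studies)


def load_periodontal() -> MVDataset:
    """The bundled five-study periodontal dataset (probing depth and
    attachment level improvement in mm, full within-study covariances)."""
    ref = resources.files("mvhet").joinpath("data/berkey1998.csv")
    with resources.as_file(ref) as path:
        return read_wide_berkey(path, outcome_names=("probing_depth", "attachment_level"))


# ---------------------------------------------------------------------------
# Report serialisation


def fit_to_dict(fit) -> dict:
    return {
        "schema_version": 1,
        "beta": np.asarray(fit.beta).tolist(),
        "se": np.asarray(fit.se()).tolist(),
        "beta_names": list(fit.beta_names),
        "C": np.asarray(fit.C).tolist(),
        "Sigma": np.asarray(fit.Sigma).tolist(),
        "method": fit.method,
        "cov_method": fit.cov_method,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
    }


def write_report_json(obj, path) -> None:
    """Write a fit or heterogeneity report as JSON (full precision)."""
    if isinstance(obj, HeterogeneityReport):
        payload = obj.to_dict()
    elif hasattr(obj, "beta"):
        payload = fit_to_dict(obj)
    else:
        payload = obj
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def write_report_csv(report: HeterogeneityReport, path) -> None:
    """Flat one-row-per-statistic CSV of a heterogeneity report."""
    pd.DataFrame(report.to_rows()).to_csv(path, index=False)
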