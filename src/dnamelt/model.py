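"""Log-linear melting-temperature model and its regression machinery.

The melting temperature of a duplex is modelled as

    Tm = a_E * E + a_len * ln(Len) + a_salt * ln(Conc) + a_dna * ln(DNA) + b

where E is the per-base dinucleotide strength parameter, Len the sequence
length in bases, Conc the Na+ concentration (molar) and DNA the total
nucleotide strand concentration (molar for oligonucleotides; genomic
experiments customarily report g/ml and the value is used as given, with
only a unit tag recorded).  All logarithms are natural.

Published coefficients are provided; the same design matrix can be refit
by ordinary least squares on any dataset of (sequence, conditions,
experimental Tm) records through :class:`TmRegression`, a model object
whose :meth:`TmRegression.fit` returns a :class:`TmRegressionResults`
carrying estimates, standard errors, fit statistics and a summary table.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .strength import normalize_sequence, strength_per_base

__all__ = [
    "MeltingConditions",
    "ModelCoefficients",
    "TmDatasetRecord",
    "published_coefficients",
    "predict_tm",
    "predict_tm_for_sequence",
    "TmRegression",
    "TmRegressionResults",
    "EvaluationResult",
    "records_to_frame",
    "frame_to_records",
]

StrandUnits = Literal["molar", "g_per_ml"]


@dataclass(frozen=True)
class MeltingConditions:
    """Solution conditions entering the model.

    na_molar
        Na+ concentration in mol/l; enters as ln(na_molar).
    strand_conc
        Total nucleotide strand concentration; enters as ln(strand_conc)
        in whatever unit it is reported in (see ``strand_conc_units``).
    strand_conc_units
        "molar" (oligonucleotide convention) or "g_per_ml" (genomic
        convention).  A tag only — no conversion is applied.
    """

    na_molar: float
    strand_conc: float
    strand_conc_units: StrandUnits = "molar"

    def __post_init__(self) -> None:
        if not self.na_molar > 0:
            raise ValueError(f"na_molar must be > 0 (got {self.na_molar}); it enters a natural log")
        if not self.strand_conc > 0:
            raise ValueError(
                f"strand_conc must be > 0 (got {self.strand_conc}); it enters a natural log"
            )
        if self.strand_conc_units not in ("molar", "g_per_ml"):
            raise ValueError(f"unknown strand_conc_units {self.strand_conc_units!r}")


@dataclass(frozen=True)
class ModelCoefficients:
    """Coefficients of the log-linear Tm equation.

    ``variant`` is "four_term" for the full model or "three_term_no_dna"
    for the strand-concentration-free variant (``a_dna`` is then None).
    """

    a_e: float
    a_len: float
    a_salt: float
    intercept: float
    a_dna: float | None = None
    variant: str = "four_term"

    def __post_init__(self) -> None:
        if self.variant == "four_term" and self.a_dna is None:
            raise ValueError("four_term coefficients require a_dna")
        if self.variant == "three_term_no_dna" and self.a_dna is not None:
            raise ValueError("three_term_no_dna coefficients must not carry a_dna")

    def as_dict(self) -> dict[str, float]:
        d = {"a_e": self.a_e, "a_len": self.a_len, "a_salt": self.a_salt,
             "intercept": self.intercept, "variant": self.variant}
        if self.a_dna is not None:
            d["a_dna"] = self.a_dna
        return d


#: Coefficients of the published four-term equation.
_PUBLISHED = ModelCoefficients(
    a_e=7.35, a_len=17.34, a_salt=4.96, a_dna=0.89, intercept=-25.42
)


def published_coefficients() -> ModelCoefficients:
    """The published four-term coefficients of the melting-temperature equation."""
    return _PUBLISHED


def predict_tm(
    e: float,
    length: int,
    conditions: MeltingConditions,
    coefficients: ModelCoefficients | None = None,
) -> float:
    """Evaluate the Tm equation for a per-base strength E and a length in bases."""
    if coefficients is None:
        coefficients = _PUBLISHED
    if length < 2:
        raise ValueError(f"length must be >= 2 (got {length})")
    tm = (
        coefficients.a_e * e
        + coefficients.a_len * math.log(length)
        + coefficients.a_salt * math.log(conditions.na_molar)
        + coefficients.intercept
    )
    if coefficients.variant == "four_term":
        assert coefficients.a_dna is not None
        tm += coefficients.a_dna * math.log(conditions.strand_conc)
    return tm


def predict_tm_for_sequence(
    seq: str,
    conditions: MeltingConditions,
    coefficients: ModelCoefficients | None = None,
    round_e_2dp: bool = False,
) -> float:
    """Score a sequence and evaluate the Tm equation.

    ``round_e_2dp`` rounds E to two decimals first, matching the
    hand-calculation convention; default is full precision.
    """
    seq = normalize_sequence(seq, min_length=2)
    e = strength_per_base(seq, round_2dp=round_e_2dp)
    return predict_tm(e, len(seq), conditions, coefficients)


@dataclass
class TmDatasetRecord:
    """One (sequence, conditions, experimental Tm) observation."""

    id: str
    sequence: str
    conditions: MeltingConditions
    exp_tm: float | None = None
    pred_tm: float | None = None

    @property
    def residual(self) -> float | None:
        if self.exp_tm is None or self.pred_tm is None:
            return None
        return self.exp_tm - self.pred_tm


_PREDICTOR_COLS = {"e": "E", "len": "ln(Len)", "salt": "ln(Conc)", "dna": "ln(DNA)"}


def records_to_frame(records: Iterable[TmDatasetRecord]) -> pd.DataFrame:
    """Flatten records into the canonical dataset DataFrame."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "sequence": r.sequence,
                "na_molar": r.conditions.na_molar,
                "strand_conc": r.conditions.strand_conc,
                "strand_conc_units": r.conditions.strand_conc_units,
                "exp_tm": np.nan if r.exp_tm is None else r.exp_tm,
                "pred_tm": np.nan if r.pred_tm is None else r.pred_tm,
            }
        )
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[TmDatasetRecord]:
    """Build typed records from a dataset DataFrame (see :func:`dnamelt.io.read_dataset`)."""
    records = []
    for _, row in df.iterrows():
        exp = row.get("exp_tm")
        records.append(
            TmDatasetRecord(
                id=str(row["id"]),
                sequence=str(row["sequence"]),
                conditions=MeltingConditions(
                    na_molar=float(row["na_molar"]),
                    strand_conc=float(row["strand_conc"]),
                    strand_conc_units=str(row.get("strand_conc_units", "molar")),
                ),
                exp_tm=None if exp is None or (isinstance(exp, float) and math.isnan(exp)) else float(exp),
            )
        )
    return records


def _design_frame(records: Sequence[TmDatasetRecord]) -> pd.DataFrame:
    """Transformed predictors (E, ln Len, ln Conc, ln DNA) plus exp_tm per record."""
    rows = []
    for r in records:
        seq = normalize_sequence(r.sequence, min_length=2)
        rows.append(
            {
                "e": strength_per_base(seq),
                "len": math.log(len(seq)),
                "salt": math.log(r.conditions.na_molar),
                "dna": math.log(r.conditions.strand_conc),
                "exp_tm": np.nan if r.exp_tm is None else r.exp_tm,
                "n_bases": len(seq),
            }
        )
    return pd.DataFrame(rows)


class TmRegression:
    """Ordinary-least-squares refit of the Tm equation on a dataset.

    Built from :class:`TmDatasetRecord` observations (or a dataset
    DataFrame via :meth:`from_dataframe`).  ``fit`` regresses the
    experimental Tm on [E, ln Len, ln Conc, (ln DNA)] with intercept;
    ``evaluate`` applies fixed coefficients without refitting;
    ``parameter_combination_correlations`` reports the correlation
    between fitted and experimental Tm for every non-empty predictor
    subset.
    """

    def __init__(self, records: Sequence[TmDatasetRecord]):
        self.records = list(records)
        if not self.records:
            raise ValueError("empty dataset")
        self._design = _design_frame(self.records)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TmRegression":
        return cls(frame_to_records(df))

    # -- fitting ---------------------------------------------------------

    def _fit_ols(self, predictors: Sequence[str]):
        mask = self._design["exp_tm"].notna()
        if int(mask.sum()) < len(predictors) + 2:
            raise ValueError(
                f"need at least {len(predictors) + 2} records with exp_tm to fit "
                f"{len(predictors)} predictors + intercept (have {int(mask.sum())})"
            )
        x = self._design.loc[mask, list(predictors)]
        x = sm.add_constant(x, has_constant="add")
        y = self._design.loc[mask, "exp_tm"]
        rank = np.linalg.matrix_rank(x.to_numpy())
        if rank < x.shape[1]:
            raise ValueError(
                "rank-deficient design matrix: predictors "
                f"{list(predictors)} are collinear on this dataset"
            )
        return sm.OLS(y, x).fit()

    def fit(self, variant: str = "four_term") -> "TmRegressionResults":
        """Refit the equation's coefficients by OLS; deterministic."""
        predictors = ["e", "len", "salt"] + (["dna"] if variant == "four_term" else [])
        if variant not in ("four_term", "three_term_no_dna"):
            raise ValueError(f"unknown variant {variant!r}")
        res = self._fit_ols(predictors)
        p = res.params
        coefficients = ModelCoefficients(
            a_e=float(p["e"]),
            a_len=float(p["len"]),
            a_salt=float(p["salt"]),
            a_dna=float(p["dna"]) if variant == "four_term" else None,
            intercept=float(p["const"]),
            variant=variant,
        )
        return TmRegressionResults(model=self, coefficients=coefficients, _sm_results=res)

    # -- evaluation without refitting ------------------------------------

    def evaluate(self, coefficients: ModelCoefficients | None = None) -> "EvaluationResult":
        """Fill predictions under fixed coefficients and compute fit statistics."""
        if coefficients is None:
            coefficients = _PUBLISHED
        d = self._design
        pred = (
            coefficients.a_e * d["e"]
            + coefficients.a_len * d["len"]
            + coefficients.a_salt * d["salt"]
            + coefficients.intercept
        )
        if coefficients.variant == "four_term":
            pred = pred + coefficients.a_dna * d["dna"]
        pred = pred.to_numpy()
        for rec, p in zip(self.records, pred):
            rec.pred_tm = float(p)
        exp = d["exp_tm"].to_numpy()
        mask = ~np.isnan(exp)
        if not mask.any():
            raise ValueError("no records carry an experimental Tm to evaluate against")
        return EvaluationResult._from_arrays(exp[mask], pred[mask], coefficients, self)

    # -- predictor-subset correlations -----------------------------------

    def parameter_combination_correlations(self) -> pd.DataFrame:
        """Correlation with experimental Tm for all 15 non-empty predictor subsets.

        Multi-predictor subsets report the (non-negative) correlation of
        the OLS-fitted Tm with the experimental Tm; single-predictor
        subsets report the signed simple correlation, preserving the
        direction of the raw association.
        """
        names = {"e": "E", "len": "Len", "salt": "Conc", "dna": "DNA"}
        d = self._design
        mask = d["exp_tm"].notna()
        y = d.loc[mask, "exp_tm"]
        rows = []
        for k in range(1, 5):
            for subset in itertools.combinations(["e", "len", "salt", "dna"], k):
                res = self._fit_ols(subset)
                r = math.sqrt(max(res.rsquared, 0.0))
                if k == 1:
                    sign = np.sign(np.corrcoef(d.loc[mask, subset[0]], y)[0, 1])
                    r *= 1 if sign >= 0 else -1
                rows.append(
                    {"parameters": " + ".join(names[s] for s in subset), "r": r}
                )
        return pd.DataFrame(rows)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("correlation undefined for degenerate data; reporting NaN")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class EvaluationResult:
    """Agreement statistics between predicted and experimental Tm."""

    coefficients: ModelCoefficients
    r: float
    r2: float
    mean_abs_error: float
    std_error_of_estimate: float
    residuals: np.ndarray = field(repr=False)
    n: int = 0
    model: "TmRegression | None" = field(default=None, repr=False)

    @classmethod
    def _from_arrays(cls, exp, pred, coefficients, model=None) -> "EvaluationResult":
        resid = exp - pred
        r = _pearson(exp, pred)
        # std error of estimate: RMS residual about the fitted line
        see = float(np.sqrt(np.mean(resid**2))) if len(resid) else float("nan")
        return cls(
            coefficients=coefficients,
            r=r,
            r2=r * r if not math.isnan(r) else float("nan"),
            mean_abs_error=float(np.mean(np.abs(resid))),
            std_error_of_estimate=see,
            residuals=resid,
            n=len(resid),
            model=model,
        )

    def normal_probability_plot_data(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted residuals against standard-normal plotting-position quantiles."""
        from scipy import stats

        sorted_resid = np.sort(self.residuals)
        n = len(sorted_resid)
        quantiles = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        return quantiles, sorted_resid


class TmRegressionResults:
    """Results of an OLS refit: coefficients, uncertainties and diagnostics."""

    def __init__(self, model: TmRegression, coefficients: ModelCoefficients, _sm_results):
        self.model = model
        self.coefficients = coefficients
        self._sm = _sm_results
        self.evaluation = model.evaluate(coefficients)

    @property
    def params(self) -> pd.Series:
        return self._sm.params

    @property
    def bse(self) -> pd.Series:
        """Standard errors of the coefficient estimates."""
        return self._sm.bse

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self._sm.conf_int(alpha=alpha)

    @property
    def r(self) -> float:
        return self.evaluation.r

    @property
    def rsquared(self) -> float:
        return float(self._sm.rsquared)

    @property
    def mean_abs_error(self) -> float:
        return self.evaluation.mean_abs_error

    @property
    def std_error_of_estimate(self) -> float:
        return self.evaluation.std_error_of_estimate

    @property
    def resid(self) -> np.ndarray:
        return self.evaluation.residuals

    def summary(self) -> str:
        c = self.coefficients
        lines = [
            "Tm regression (OLS on E, ln Len, ln Conc"
            + (", ln DNA)" if c.variant == "four_term" else ") — no DNA term"),
            f"  n = {self.evaluation.n}",
            f"  a_E      = {c.a_e:10.4f}  (se {self.bse['e']:.4f})",
            f"  a_len    = {c.a_len:10.4f}  (se {self.bse['len']:.4f})",
            f"  a_salt   = {c.a_salt:10.4f}  (se {self.bse['salt']:.4f})",
        ]
        if c.variant == "four_term":
            lines.append(f"  a_DNA    = {c.a_dna:10.4f}  (se {self.bse['dna']:.4f})")
        lines += [
            f"  intercept= {c.intercept:10.4f}  (se {self.bse['const']:.4f})",
            f"  r = {self.r:.4f}   r^2 = {self.rsquared:.4f}",
            f"  mean |error| = {self.mean_abs_error:.4f} degC",
            f"  std error of estimate = {self.std_error_of_estimate:.4f} degC",
        ]
        return "\n".join(lines)
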