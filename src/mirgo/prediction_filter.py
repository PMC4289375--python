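"""Posterior-probability filtering of predicted miRNA-target context scores.

Raw target-prediction context scores (more negative = stronger predicted
repression) are modelled as a two-component mixture: a *valid* component,
calibrated on the scores of empirically validated interactions, and a
*background* component covering the remaining predictions.  Each prediction
then receives the posterior probability of belonging to the valid component,

    P(valid | s) = pi f_v(s) / (pi f_v(s) + (1 - pi) f_b(s)),

and only predictions with posterior above a threshold (default 0.98) are
kept.

Two fitting families are provided.  ``gaussian`` fits the valid component by
maximum likelihood on the validated scores, then estimates the background
Gaussian and the mixing weight ``pi`` by expectation-maximisation on the
predicted-score population with the valid component held fixed.
``gaussian_mixture`` fits an unconstrained two-component Gaussian mixture to
the pooled predicted scores (for the case where no clean validated sample
exists) and labels as "valid" the component whose mean is closer to the
validated-score mean.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from mirgo.interactions import Interaction, InteractionSet, Source

__all__ = [
    "ScoredPrediction",
    "ScoreModel",
    "FilterReport",
    "fit_score_model",
    "posterior_validity",
    "filter_predictions",
    "read_predictions",
    "write_predictions",
]


@dataclass
class ScoredPrediction:
    """A predicted (miRNA, gene) pair with its context score.

    ``posterior`` is filled in by the filter; ``label`` optionally records a
    known ground-truth class ("valid"/"background") on synthetic data.
    """

    mirna: str
    gene: str
    score: float
    posterior: float | None = None
    label: str | None = None


class NotFittedError(RuntimeError):
    pass


class ScoreModel:
    """Two-component score model assigning posterior validity probabilities.

    Estimator-style interface: construct with hyperparameters, call
    :meth:`fit` with score samples, then :meth:`posterior` on new scores.

    Parameters
    ----------
    family : {"gaussian", "gaussian_mixture"}
        Fitting strategy (see module docstring).
    threshold : float
        Posterior probability above which a prediction is kept.
    prior : float, optional
        User-supplied mixing weight pi overriding the estimate.
    max_iter, tol : EM stopping rule.

    Attributes (after fit)
    ----------------------
    valid_mean_, valid_sd_ : parameters of the valid component.
    bg_mean_, bg_sd_ : parameters of the background component.
    prior_valid_ : estimated (or user-fixed) mixing weight pi.
    identifiable_ : False when the two components are too similar for the
        mixture to be identifiable; posteriors are then uninformative.
    n_dropped_ : number of non-finite input scores rejected during fitting.
    """

    _MIN_SD = 1e-9

    def __init__(
        self,
        family: str = "gaussian",
        threshold: float = 0.98,
        prior: float | None = None,
        max_iter: int = 500,
        tol: float = 1e-10,
    ) -> None:
        if family not in ("gaussian", "gaussian_mixture"):
            raise ValueError(f"unknown family {family!r}")
        if not 0.0 < threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if prior is not None and not 0.0 < prior < 1.0:
            raise ValueError("prior must be in (0, 1)")
        self.family = family
        self.threshold = threshold
        self.prior = prior
        self.max_iter = max_iter
        self.tol = tol

    # -- sklearn-style plumbing -------------------------------------------
    def get_params(self) -> dict:
        return {
            "family": self.family,
            "threshold": self.threshold,
            "prior": self.prior,
            "max_iter": self.max_iter,
            "tol": self.tol,
        }

    def set_params(self, **params) -> "ScoreModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    @property
    def is_fitted(self) -> bool:
        return hasattr(self, "prior_valid_")

    def _check_fitted(self) -> None:
        if not self.is_fitted:
            raise NotFittedError("ScoreModel must be fitted first")

    # -- fitting ----------------------------------------------------------
    @staticmethod
    def _clean(scores, what: str, min_n: int = 30):
        x = np.asarray(scores, dtype=float).ravel()
        finite = np.isfinite(x)
        dropped = int((~finite).sum())
        x = x[finite]
        if x.size < min_n:
            raise ValueError(f"need >= {min_n} finite {what} scores, got {x.size}")
        if np.ptp(x) == 0.0:
            raise ValueError(f"degenerate {what} scores: all values identical")
        return x, dropped

    def fit(self, validated_scores, predicted_scores) -> "ScoreModel":
        """Fit the score model.

        ``validated_scores`` are context scores of empirically validated
        interactions; ``predicted_scores`` the full predicted-score
        population (ideally with validated pairs already removed).
        """
        valid, d1 = self._clean(validated_scores, "validated")
        pred, d2 = self._clean(predicted_scores, "predicted")
        self.n_dropped_ = d1 + d2
        if self.n_dropped_:
            warnings.warn(f"rejected {self.n_dropped_} non-finite scores", stacklevel=2)

        if self.family == "gaussian":
            self._fit_fixed_valid_em(valid, pred)
        else:
            self._fit_gmm(valid, pred)

        sep = abs(self.valid_mean_ - self.bg_mean_)
        pooled_sd = float(np.std(np.concatenate([valid, pred])))
        self.identifiable_ = bool(sep > 0.1 * max(pooled_sd, self._MIN_SD))
        if not self.identifiable_:
            warnings.warn(
                "valid and background score distributions are nearly identical; "
                "the mixing weight is not identifiable and posteriors are "
                "uninformative",
                stacklevel=2,
            )
        return self

    def _fit_fixed_valid_em(self, valid: np.ndarray, pred: np.ndarray) -> None:
        self.valid_mean_ = float(valid.mean())
        self.valid_sd_ = float(max(valid.std(), self._MIN_SD))
        # init background from the bulk of predictions, pi small
        bg_mean = float(np.median(pred))
        bg_sd = float(max(1.4826 * np.median(np.abs(pred - bg_mean)), self._MIN_SD))
        pi = 0.2 if self.prior is None else self.prior
        log_fv = norm.logpdf(pred, self.valid_mean_, self.valid_sd_)
        prev = -np.inf
        for _ in range(self.max_iter):
            log_fb = norm.logpdf(pred, bg_mean, bg_sd)
            a = np.log(pi) + log_fv
            b = np.log1p(-pi) + log_fb
            m = np.maximum(a, b)
            log_mix = m + np.log(np.exp(a - m) + np.exp(b - m))
            resp = np.exp(a - log_mix)  # responsibility of the valid component
            ll = float(log_mix.sum())
            w = 1.0 - resp
            wsum = w.sum()
            if wsum <= 0:
                break
            bg_mean = float((w * pred).sum() / wsum)
            bg_sd = float(
                max(np.sqrt((w * (pred - bg_mean) ** 2).sum() / wsum), self._MIN_SD)
            )
            if self.prior is None:
                pi = float(np.clip(resp.mean(), 1e-6, 1 - 1e-6))
            if abs(ll - prev) < self.tol * max(1.0, abs(ll)):
                break
            prev = ll
        self.bg_mean_ = bg_mean
        self.bg_sd_ = bg_sd
        self.prior_valid_ = float(pi)

    def _fit_gmm(self, valid: np.ndarray, pred: np.ndarray) -> None:
        from sklearn.mixture import GaussianMixture

        gmm = GaussianMixture(n_components=2, random_state=0, n_init=3)
        gmm.fit(pred.reshape(-1, 1))
        means = gmm.means_.ravel()
        sds = np.sqrt(gmm.covariances_.ravel())
        weights = gmm.weights_.ravel()
        ref = float(valid.mean())
        iv = int(np.argmin(np.abs(means - ref)))
        ib = 1 - iv
        self.valid_mean_, self.valid_sd_ = float(means[iv]), float(max(sds[iv], self._MIN_SD))
        self.bg_mean_, self.bg_sd_ = float(means[ib]), float(max(sds[ib], self._MIN_SD))
        self.prior_valid_ = float(weights[iv]) if self.prior is None else self.prior

    # -- inference --------------------------------------------------------
    def posterior(self, score):
        """Posterior probability of validity for one score or an array."""
        self._check_fitted()
        s = np.asarray(score, dtype=float)
        if not np.all(np.isfinite(s)):
            raise ValueError("non-finite score")
        pi = self.prior_valid_
        a = np.log(pi) + norm.logpdf(s, self.valid_mean_, self.valid_sd_)
        b = np.log1p(-pi) + norm.logpdf(s, self.bg_mean_, self.bg_sd_)
        m = np.maximum(a, b)
        post = np.exp(a - m) / (np.exp(a - m) + np.exp(b - m))
        return float(post) if np.isscalar(score) else post

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "family": self.family,
            "threshold": self.threshold,
            "valid_component": {"mean": self.valid_mean_, "sd": self.valid_sd_},
            "background_component": {"mean": self.bg_mean_, "sd": self.bg_sd_},
            "prior_valid": self.prior_valid_,
            "identifiable": self.identifiable_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreModel":
        model = cls(family=d["family"], threshold=d["threshold"])
        model.valid_mean_ = float(d["valid_component"]["mean"])
        model.valid_sd_ = float(d["valid_component"]["sd"])
        model.bg_mean_ = float(d["background_component"]["mean"])
        model.bg_sd_ = float(d["background_component"]["sd"])
        model.prior_valid_ = float(d["prior_valid"])
        model.identifiable_ = bool(d.get("identifiable", True))
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "ScoreModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_score_model(
    validated_scores,
    all_predicted_scores,
    family: str = "gaussian",
    threshold: float = 0.98,
    prior: float | None = None,
) -> ScoreModel:
    """Fit a :class:`ScoreModel` (functional wrapper around the class)."""
    return ScoreModel(family=family, threshold=threshold, prior=prior).fit(
        validated_scores, all_predicted_scores
    )


def posterior_validity(score: float, model: ScoreModel) -> float:
    """P(valid | score) under a fitted model."""
    return model.posterior(score)


@dataclass
class FilterReport:
    """Before/after accounting of a posterior filter pass."""

    threshold: float
    n_input: int
    n_kept: int
    n_dropped: int
    genes_before: int
    genes_after: int
    mirnas_before: int
    mirnas_after: int
    model: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def filter_predictions(
    predictions: list[ScoredPrediction],
    model: ScoreModel,
    threshold: float | None = None,
    name: str = "predicted_filtered",
) -> tuple[InteractionSet, FilterReport]:
    """Keep predictions whose posterior validity exceeds the threshold.

    Returns the kept predictions as an :class:`InteractionSet` (source
    ``PREDICTED``) and a :class:`FilterReport` with before/after counts.
    Every input prediction gets its ``posterior`` attribute filled in.
    """
    model._check_fitted()
    thr = model.threshold if threshold is None else threshold
    kept = InteractionSet(name=name)
    n_kept = 0
    for p in predictions:
        p.posterior = model.posterior(p.score)
        if p.posterior > thr:
            kept.add(
                Interaction(p.mirna, p.gene, Source.PREDICTED, f"posterior={p.posterior:.6f}")
            )
            n_kept += 1
    genes_before = {p.gene for p in predictions}
    mirnas_before = {p.mirna for p in predictions}
    report = FilterReport(
        threshold=thr,
        n_input=len(predictions),
        n_kept=n_kept,
        n_dropped=len(predictions) - n_kept,
        genes_before=len(genes_before),
        genes_after=len(kept.genes()),
        mirnas_before=len(mirnas_before),
        mirnas_after=len(kept.mirnas()),
        model=model.to_dict(),
    )
    return kept, report


def read_predictions(path) -> list[ScoredPrediction]:
    """Read the predicted dialect (``mirna, gene, context_score`` TSV)."""
    import pandas as pd

    from mirgo.interactions import FormatError

    df = pd.read_csv(path, sep="\t", dtype={"mirna": str, "gene": str})
    for col in ("mirna", "gene", "context_score"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    out = []
    for row in df.itertuples(index=False):
        gene = str(row.gene).strip().upper()
        mirna = str(row.mirna).strip()
        if mirna and gene:
            label = getattr(row, "label", None)
            out.append(
                ScoredPrediction(mirna, gene, float(row.context_score), label=label)
            )
    return out


def write_predictions(predictions: list[ScoredPrediction], path) -> None:
    import pandas as pd

    rows = [
        {
            "mirna": p.mirna,
            "gene": p.gene,
            "context_score": p.score,
            **({"posterior": p.posterior} if p.posterior is not None else {}),
            **({"label": p.label} if p.label is not None else {}),
        }
        for p in predictions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
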