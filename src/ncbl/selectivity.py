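"""Feature-selectivity analysis of single units (scenario: suboptimal features).

A unit's selectivity is summarized two ways: a per-class mean-response
profile, and an ordinary-least-squares fit of the unit's activation on
one-hot class indicators.  The design is fit without an intercept so all K
indicators are estimable; for this orthogonal design each coefficient is
exactly the class mean, and the per-feature explained variance (drop-one
semi-partial R^2 against the uncentered total sum of squares) sums exactly
to the model R^2.

``excluded_class_analysis`` re-runs the regression with one class removed
from the stimulus set, exposing the suboptimal-selectivity error: when the
truly optimal class is absent, the top coefficient migrates to the most
confusable remaining class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ncbl.dnn_model import ActivationMatrix

__all__ = [
    "SelectivityProfile",
    "RegressionResult",
    "ExcludedClassReport",
    "selectivity_profile",
    "onehot_regression",
    "excluded_class_analysis",
]


@dataclass(frozen=True)
class SelectivityProfile:
    """Per-class mean activation of one unit."""

    unit_id: int
    class_ids: np.ndarray
    class_means: np.ndarray
    class_counts: np.ndarray

    def top_class(self) -> int:
        return int(self.class_ids[np.argmax(self.class_means)])


@dataclass(frozen=True)
class RegressionResult:
    """No-intercept OLS of a unit's activation on one-hot class indicators."""

    class_ids: np.ndarray
    coefficients: np.ndarray
    p_values: np.ndarray
    explained_variance: np.ndarray
    total_r2: float
    residual_df: int

    def top_feature(self) -> int:
        """Class id with the largest coefficient (= largest class mean)."""
        return int(self.class_ids[np.argmax(self.coefficients)])


@dataclass(frozen=True)
class ExcludedClassReport:
    full: RegressionResult
    reduced: RegressionResult
    top_feature_full: int
    top_feature_reduced: int

    @property
    def selectivity_changed(self) -> bool:
        """True when excluding the class flips the apparent optimal feature."""
        return self.top_feature_full != self.top_feature_reduced


def selectivity_profile(acts: ActivationMatrix, unit_id: int) -> SelectivityProfile:
    """Average the unit's activation within each presented class."""
    if not 0 <= unit_id < acts.n_units:
        raise ValueError(f"unit_id {unit_id} out of range [0, {acts.n_units})")
    y = acts.values[:, unit_id]
    class_ids = np.unique(acts.trial_labels)
    means = np.array([y[acts.trial_labels == c].mean() for c in class_ids])
    counts = np.array([(acts.trial_labels == c).sum() for c in class_ids])
    return SelectivityProfile(
        unit_id=unit_id, class_ids=class_ids, class_means=means, class_counts=counts
    )


def onehot_regression(
    acts: ActivationMatrix,
    unit_id: int,
    included_classes: "set[int] | list[int] | None" = None,
) -> RegressionResult:
    """OLS of the unit's activation on one-hot indicators, no intercept.

    Coefficients carry two-sided t-test p-values with
    ``residual_df = n - (#included classes)``; per-feature explained
    variance is the drop-one semi-partial ``(RSS_without_j - RSS_full)/TSS``
    with the uncentered TSS appropriate for a no-intercept fit.  A
    zero-variance (constant) response returns zero explained variance,
    zero R^2 and p-values of 1 so degenerate inputs stay total.
    """
    if not 0 <= unit_id < acts.n_units:
        raise ValueError(f"unit_id {unit_id} out of range [0, {acts.n_units})")
    present = np.unique(acts.trial_labels)
    if included_classes is None:
        class_ids = present
    else:
        class_ids = np.array(sorted(set(included_classes)), dtype=int)
        if class_ids.size == 0:
            raise ValueError("included_classes is empty")
        missing = set(class_ids) - set(present)
        if missing:
            raise ValueError(f"classes {sorted(missing)} have no trials")

    mask = np.isin(acts.trial_labels, class_ids)
    y = acts.values[mask, unit_id]
    labels = acts.trial_labels[mask]
    n = y.shape[0]
    J = class_ids.size
    counts = np.array([(labels == c).sum() for c in class_ids])
    if (counts < 2).any():
        bad = class_ids[counts < 2].tolist()
        raise ValueError(f"classes {bad} have fewer than 2 trials")

    # orthogonal one-hot design: beta_j = class-j mean, exactly
    beta = np.array([y[labels == c].mean() for c in class_ids])
    fitted = beta[np.searchsorted(class_ids, labels)]
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum(y**2))
    df = n - J

    if np.ptp(y) == 0.0:
        return RegressionResult(
            class_ids=class_ids,
            coefficients=beta,
            p_values=np.ones(J),
            explained_variance=np.zeros(J),
            total_r2=0.0,
            residual_df=df,
        )

    sigma2 = rss / df if df > 0 else np.nan
    se = np.sqrt(sigma2 / counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df) if df > 0 else np.full(J, np.nan)

    # dropping indicator j forces class-j fits to zero: RSS grows by n_j * beta_j^2
    ev = counts * beta**2 / tss if tss > 0 else np.zeros(J)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return RegressionResult(
        class_ids=class_ids,
        coefficients=beta,
        p_values=np.asarray(p),
        explained_variance=ev,
        total_r2=float(r2),
        residual_df=df,
    )


def excluded_class_analysis(
    acts: ActivationMatrix, unit_id: int, excluded_class: int
) -> ExcludedClassReport:
    """Contrast the regression with and without one class in the stimulus set."""
    present = set(np.unique(acts.trial_labels).tolist())
    if excluded_class not in present:
        raise ValueError(f"excluded class {excluded_class} not present in data")
    full = onehot_regression(acts, unit_id, included_classes=present)
    reduced = onehot_regression(
        acts, unit_id, included_classes=present - {excluded_class}
    )
    return ExcludedClassReport(
        full=full,
        reduced=reduced,
        top_feature_full=full.top_feature(),
        top_feature_reduced=reduced.top_feature(),
    )
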