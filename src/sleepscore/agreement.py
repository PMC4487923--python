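"""Scorer-agreement statistics: percent agreement, Cohen's kappa with a
95% confidence interval, and the per-state confusion matrix.

Cohen's kappa corrects raw agreement for chance:

    kappa = (p_o - p_e) / (1 - p_e)

with observed agreement p_o = trace(confusion)/n and expected agreement
p_e from the product of the two scorers' marginal proportions. The
default confidence interval uses the large-sample standard error of
Fleiss, Cohen & Everitt; a nonparametric bootstrap is available as a
cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ScoredMatrix, State

__all__ = ["AgreementReport", "compare", "compare_labels", "cohens_kappa"]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class AgreementReport:
    percent_agreement: float  # in [0, 100]
    kappa: float
    kappa_ci: tuple[float, float]  # 95%
    confusion: np.ndarray  # counts, rows = scorer A, cols = scorer B
    labels: tuple[State, ...]
    n_compared: int

    def to_dict(self) -> dict:
        return {
            "percent_agreement": self.percent_agreement,
            "kappa": self.kappa,
            "kappa_ci": list(self.kappa_ci),
            "labels": [s.name for s in self.labels],
            "confusion": self.confusion.tolist(),
            "n_compared": self.n_compared,
        }

    def __str__(self) -> str:
        lo, hi = self.kappa_ci
        lines = [
            f"n compared epochs : {self.n_compared}",
            f"percent agreement : {self.percent_agreement:.1f}%",
            f"Cohen's kappa     : {self.kappa:.3f} (95% CI {lo:.3f}-{hi:.3f})",
            "confusion (rows = scorer A, cols = scorer B):",
            "          " + "  ".join(f"{s.name:>8}" for s in self.labels),
        ]
        for s, row in zip(self.labels, self.confusion):
            lines.append(f"{s.name:>8}  " + "  ".join(f"{c:8d}" for c in row))
        return "\n".join(lines)


def _kappa_from_confusion(confusion: np.ndarray) -> tuple[float, float, float]:
    """Return (kappa, p_o, p_e) from a square count matrix."""
    n = confusion.sum()
    p = confusion / n
    p_o = float(np.trace(p))
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_e = float(row @ col)
    if p_e >= 1.0:
        # both scorers constant on the same label: chance correction is
        # undefined; perfect agreement is reported as kappa 1
        warnings.warn("degenerate marginals (p_e = 1)", stacklevel=3)
        return (1.0 if p_o == 1.0 else 0.0), p_o, p_e
    return (p_o - p_e) / (1.0 - p_e), p_o, p_e


def _kappa_se(confusion: np.ndarray) -> float:
    """Large-sample standard error of kappa (Fleiss-Cohen-Everitt)."""
    n = confusion.sum()
    p = confusion / n
    kappa, _, p_e = _kappa_from_confusion(confusion)
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    one_minus_k = 1.0 - kappa
    a = sum(
        p[i, i] * (1.0 - (row[i] + col[i]) * one_minus_k) ** 2
        for i in range(len(p))
    )
    b = one_minus_k**2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(len(p))
        for j in range(len(p))
        if i != j
    )
    c = (kappa - p_e * one_minus_k) ** 2
    var = (a + b - c) / (n * (1.0 - p_e) ** 2)
    return float(np.sqrt(max(var, 0.0)))


def cohens_kappa(confusion: np.ndarray) -> float:
    """Cohen's kappa from a square confusion-count matrix."""
    confusion = np.asarray(confusion, dtype=np.float64)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    if confusion.sum() <= 0:
        raise ValueError("confusion matrix has no counts")
    return _kappa_from_confusion(confusion)[0]


def compare_labels(
    a: np.ndarray,
    b: np.ndarray,
    labels: tuple[State, ...] = (State.WAKE, State.NREMS, State.REMS),
    ci_method: str = "asymptotic",
    n_boot: int = 1000,
    seed: int = 0,
) -> AgreementReport:
    """Agreement report for two equal-length integer label sequences.

    ``ci_method`` is ``"asymptotic"`` (Fleiss-Cohen-Everitt standard
    error) or ``"bootstrap"`` (percentile interval over epoch
    resampling).
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if a.size != b.size:
        raise ValueError(f"label sequences differ in length: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("no epochs to compare")

    codes = np.array([s.value for s in labels])
    if not (np.isin(a, codes).all() and np.isin(b, codes).all()):
        raise ValueError("labels outside the compared state set")

    k = len(codes)
    code_to_pos = {int(c): i for i, c in enumerate(codes)}
    ai = np.array([code_to_pos[int(v)] for v in a])
    bi = np.array([code_to_pos[int(v)] for v in b])
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (ai, bi), 1)

    kappa, p_o, _ = _kappa_from_confusion(confusion)
    if ci_method == "asymptotic":
        se = _kappa_se(confusion)
        ci = (max(kappa - _Z95 * se, -1.0), min(kappa + _Z95 * se, 1.0))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        stats = []
        for _ in range(n_boot):
            idx = rng.integers(0, a.size, size=a.size)
            cb = np.zeros((k, k), dtype=np.int64)
            np.add.at(cb, (ai[idx], bi[idx]), 1)
            stats.append(_kappa_from_confusion(cb)[0])
        lo, hi = np.percentile(stats, [2.5, 97.5])
        ci = (float(lo), float(hi))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return AgreementReport(
        percent_agreement=100.0 * p_o,
        kappa=float(kappa),
        kappa_ci=ci,
        confusion=confusion,
        labels=tuple(labels),
        n_compared=int(a.size),
    )


def compare(
    a: ScoredMatrix,
    b: ScoredMatrix,
    exclude_artifacts: bool = True,
    ci_method: str = "asymptotic",
    n_boot: int = 1000,
    seed: int = 0,
) -> AgreementReport:
    """Agreement between two scored matrices of equal epoch count.

    With ``exclude_artifacts`` (the default, matching how agreement is
    scored over assigned vigilance states), epochs marked ARTIFACT in
    either matrix are dropped before comparison; otherwise ARTIFACT is
    treated as a fourth category.
    """
    if a.n_epochs != b.n_epochs:
        raise ValueError(
            f"epoch counts differ: {a.n_epochs} vs {b.n_epochs}"
        )
    sa, sb = a.states, b.states
    if exclude_artifacts:
        keep = (sa != State.ARTIFACT.value) & (sb != State.ARTIFACT.value)
        sa, sb = sa[keep], sb[keep]
        labels: tuple[State, ...] = (State.WAKE, State.NREMS, State.REMS)
    else:
        labels = (State.ARTIFACT, State.WAKE, State.NREMS, State.REMS)
    if sa.size == 0:
        raise ValueError("no non-artifact epochs to compare")
    return compare_labels(
        sa, sb, labels=labels, ci_method=ci_method, n_boot=n_boot, seed=seed
    )
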