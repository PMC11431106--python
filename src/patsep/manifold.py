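"""Two-neuron statistical manifold with mixed coordinates.

A pair of binary neurons observed in one time bin has four joint outcomes
(x1, x2) in {0,1}^2 with probabilities q00, q10, q01, q11.  Because the
probabilities sum to one, the family of such joint laws is a 3-D manifold.
This module implements the mixed coordinate system

    xi = (eta1, eta2, theta)

where eta_i = P(x_i = 1) is each neuron's marginal firing probability per
bin and

    theta = log( q11 * q00 / (q10 * q01) )

is the log odds ratio measuring within-ensemble correlation (0 for
independence, +/- infinity at maximal co-/anti-activation).  The marginal
block (eta1, eta2) and theta are orthogonal under the Fisher information
metric, so squared distances along d_theta and d_eta directions decouple.

The Fisher matrix is computed by differentiating the log-likelihood with
central finite differences through the coordinate-to-law map and taking
the exact expectation over the four outcomes; the squared infinitesimal
distance ds^2 = d_xi^T G d_xi then approximates twice the KL divergence
between nearby laws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "JointLaw",
    "Coordinates",
    "TangentStep",
    "FisherMatrix",
    "ThetaUndefinedError",
    "InfeasibleCoordinatesError",
    "theta_of",
    "etas_of",
    "law_of",
    "log_prob",
    "fisher_information",
    "squared_distance",
    "kl_divergence",
]

#: probabilities below this are treated as boundary (theta / G undefined)
BOUNDARY_EPS = 1e-12

#: central finite-difference step for score functions
FD_STEP = 1e-6

#: minimum distance from the feasibility boundary for Fisher computation
FISHER_BOUNDARY_MARGIN = 1e-4

# outcome order used throughout: (x1, x2) = (0,0), (1,0), (0,1), (1,1)
OUTCOMES = ((0, 0), (1, 0), (0, 1), (1, 1))


class ThetaUndefinedError(ValueError):
    """theta is infinite because some outcome probability is zero.

    ``sign`` is +1 when theta diverges to +inf (q10 or q01 -> 0) and -1
    when it diverges to -inf (q00 or q11 -> 0).
    """

    def __init__(self, message: str, sign: int):
        super().__init__(message)
        self.sign = sign


class InfeasibleCoordinatesError(ValueError):
    """No joint law exists for the requested coordinates / step."""


@dataclass(frozen=True)
class JointLaw:
    """Joint outcome probabilities of the two-neuron system.

    q_mn = P(x1 = m, x2 = n); the four entries must be in [0, 1] and sum
    to one within 1e-12.
    """

    q00: float
    q10: float
    q01: float
    q11: float

    def __post_init__(self):
        qs = self.as_array()
        if np.any(qs < -1e-15) or np.any(qs > 1 + 1e-15):
            raise ValueError(f"probabilities outside [0, 1]: {qs}")
        total = float(qs.sum())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total!r}, not 1")

    def as_array(self) -> np.ndarray:
        """Probabilities in outcome order (q00, q10, q01, q11)."""
        return np.array([self.q00, self.q10, self.q01, self.q11], float)

    def prob(self, x1: int, x2: int) -> float:
        return (self.q00, self.q01, self.q10, self.q11)[2 * x1 + x2]

    def is_interior(self, eps: float = BOUNDARY_EPS) -> bool:
        """True when all four probabilities exceed ``eps``."""
        return bool(np.all(self.as_array() > eps))

    def to_json(self) -> str:
        return json.dumps(
            {"q00": self.q00, "q10": self.q10, "q01": self.q01, "q11": self.q11}
        )

    @classmethod
    def from_json(cls, s: str) -> "JointLaw":
        d = json.loads(s)
        return cls(d["q00"], d["q10"], d["q01"], d["q11"])


@dataclass(frozen=True)
class Coordinates:
    """Mixed coordinates (eta1, eta2, theta) of a two-neuron law."""

    eta1: float
    eta2: float
    theta: float

    def __post_init__(self):
        if not (0.0 < self.eta1 < 1.0 and 0.0 < self.eta2 < 1.0):
            raise ValueError(
                f"marginals must lie strictly in (0, 1); got "
                f"({self.eta1}, {self.eta2})"
            )
        if not math.isfinite(self.theta):
            raise ValueError("theta must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.eta1, self.eta2, self.theta], float)

    def to_json(self) -> str:
        return json.dumps(
            {"eta1": self.eta1, "eta2": self.eta2, "theta": self.theta}
        )

    @classmethod
    def from_json(cls, s: str) -> "Coordinates":
        d = json.loads(s)
        return cls(d["eta1"], d["eta2"], d["theta"])


@dataclass(frozen=True)
class TangentStep:
    """Coordinate increment (d_eta1, d_eta2, d_theta)."""

    d_eta1: float = 0.0
    d_eta2: float = 0.0
    d_theta: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.d_eta1, self.d_eta2, self.d_theta], float)


@dataclass(frozen=True)
class FisherMatrix:
    """3x3 Fisher information matrix in coordinate order (eta1, eta2, theta)."""

    matrix: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.matrix, float)
        if g.shape != (3, 3):
            raise ValueError("Fisher matrix must be 3x3")
        if not np.allclose(g, g.T, atol=1e-9):
            raise ValueError("Fisher matrix must be symmetric within 1e-9")
        if np.linalg.eigvalsh(g).min() < -1e-9:
            raise ValueError("Fisher matrix must be positive semi-definite")
        object.__setattr__(self, "matrix", g)

    def __getitem__(self, ij):
        return self.matrix[ij]


def theta_of(q: JointLaw) -> float:
    """Correlation coordinate: log odds ratio of the joint law.

    Raises :class:`ThetaUndefinedError` when any outcome probability is
    zero; the error carries the sign of the divergence (-1 when q00 or
    q11 vanish, +1 when q10 or q01 vanish).
    """
    if q.q11 <= 0 or q.q00 <= 0:
        raise ThetaUndefinedError("theta undefined (infinite): -inf", sign=-1)
    if q.q10 <= 0 or q.q01 <= 0:
        raise ThetaUndefinedError("theta undefined (infinite): +inf", sign=+1)
    return math.log(q.q11 * q.q00 / (q.q10 * q.q01))


def etas_of(q: JointLaw) -> tuple[float, float]:
    """Marginal firing probabilities (eta1, eta2) = (q10+q11, q01+q11)."""
    return q.q10 + q.q11, q.q01 + q.q11


def q11_bounds(eta1: float, eta2: float) -> tuple[float, float]:
    """Feasible range of the co-activation probability at given marginals."""
    return max(0.0, eta1 + eta2 - 1.0), min(eta1, eta2)


def _law_from_marginals_q11(eta1: float, eta2: float, q11: float) -> JointLaw:
    q10 = eta1 - q11
    q01 = eta2 - q11
    q00 = 1.0 - eta1 - eta2 + q11
    # clip tiny negative round-off at the feasibility boundary
    return JointLaw(max(q00, 0.0), max(q10, 0.0), max(q01, 0.0), q11)


def law_of(c: Coordinates) -> JointLaw:
    """Joint law for mixed coordinates (inverse of theta_of/etas_of).

    With A = exp(theta), q11 solves the odds-ratio equation

        A * (eta1 - q11) * (eta2 - q11) = q11 * (1 - eta1 - eta2 + q11),

    i.e. the quadratic (A-1) q11^2 - [(A-1)(eta1+eta2) + 1] q11
    + A eta1 eta2 = 0.  theta is strictly increasing in q11 over the
    feasible interval, so the root inside
    [max(0, eta1+eta2-1), min(eta1, eta2)] is unique; it is taken
    analytically, with a bisection fallback for ill-conditioned cases.
    """
    eta1, eta2, theta = c.eta1, c.eta2, c.theta
    lo, hi = q11_bounds(eta1, eta2)
    if theta == 0.0:
        q11 = eta1 * eta2  # independence
    else:
        A = math.exp(theta)
        a = A - 1.0
        b = -(a * (eta1 + eta2) + 1.0)
        cc = A * eta1 * eta2
        disc = b * b - 4.0 * a * cc
        q11 = None
        if disc >= 0.0 and abs(a) > 1e-12:
            sq = math.sqrt(disc)
            # numerically stable pair of roots
            qq = -0.5 * (b - sq) if b < 0 else -0.5 * (b + sq)
            for root in (qq / a, cc / qq if qq != 0 else math.nan):
                if lo - 1e-12 <= root <= hi + 1e-12:
                    q11 = min(max(root, lo), hi)
                    break
        if q11 is None:
            q11 = _bisect_q11(eta1, eta2, theta, lo, hi)
    if not (lo - 1e-12 <= q11 <= hi + 1e-12):
        raise InfeasibleCoordinatesError(
            f"infeasible coordinates: no q11 in [{lo}, {hi}] for {c}"
        )
    return _law_from_marginals_q11(eta1, eta2, min(max(q11, lo), hi))


def _bisect_q11(eta1, eta2, theta, lo, hi):
    """Monotone bisection on theta(q11) - theta over the feasible interval."""

    def f(q11):
        q10 = eta1 - q11
        q01 = eta2 - q11
        q00 = 1.0 - eta1 - eta2 + q11
        if q11 <= 0 or q00 <= 0:
            return -math.inf
        if q10 <= 0 or q01 <= 0:
            return math.inf
        return math.log(q11 * q00 / (q10 * q01)) - theta

    a, b = lo, hi
    for _ in range(200):
        m = 0.5 * (a + b)
        if f(m) < 0:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def log_prob(x: tuple[int, int], c: Coordinates) -> float:
    """Log-probability of outcome x = (x1, x2) under the law at c.

    Evaluated through the log-linear expansion

        log p(x) = x1 log(q10/q00) + x2 log(q01/q00) + theta x1 x2 + log q00,

    which agrees with direct lookup of log q_{x1 x2}.  Returns -inf for a
    zero-probability outcome.
    """
    x1, x2 = x
    if x1 not in (0, 1) or x2 not in (0, 1):
        raise ValueError(f"outcome must be a binary pair, got {x}")
    q = law_of(c)
    p = q.prob(x1, x2)
    if p <= 0.0:
        return -math.inf
    return math.log(p)


def _log_probs_vector(c: Coordinates) -> np.ndarray:
    """log q over the four outcomes in OUTCOMES order."""
    q = law_of(c).as_array()
    if np.any(q <= 0):
        raise InfeasibleCoordinatesError("law has a zero outcome probability")
    return np.log(q)


def fisher_information(c: Coordinates, step: float = FD_STEP) -> FisherMatrix:
    """Fisher information matrix G at interior coordinates c.

    Score functions L_i(x) = d log p(x) / d xi_i are obtained by central
    finite differences (default step 1e-6) through :func:`law_of`; entries
    g_ij = E[L_i L_j] are exact expectations over the four outcomes
    weighted by the law at c.  The mixed-coordinate orthogonality
    g(eta1, theta) = g(eta2, theta) = 0 holds within 1e-6.
    """
    law = law_of(c)
    q = law.as_array()
    lo, hi = q11_bounds(c.eta1, c.eta2)
    margin = FISHER_BOUNDARY_MARGIN
    if (
        min(c.eta1, 1 - c.eta1, c.eta2, 1 - c.eta2) < margin
        or min(law.q11 - lo, hi - law.q11) < margin
    ):
        raise InfeasibleCoordinatesError(
            "ill-conditioned near boundary: coordinates within "
            f"{margin} of the feasibility boundary"
        )
    base = c.as_array()
    scores = np.empty((3, 4))
    for i in range(3):
        up = base.copy()
        dn = base.copy()
        up[i] += step
        dn[i] -= step
        lp_up = _log_probs_vector(Coordinates(*up))
        lp_dn = _log_probs_vector(Coordinates(*dn))
        scores[i] = (lp_up - lp_dn) / (2.0 * step)
    g = (scores * q) @ scores.T
    g = 0.5 * (g + g.T)
    return FisherMatrix(g)


def squared_distance(c: Coordinates, d: TangentStep) -> float:
    """Squared infinitesimal distance ds^2 = d^T G(c) d.

    For a step along theta only this reduces to g(theta,theta) d_theta^2;
    for steps in the marginal block it reduces to the 2x2 marginal
    quadratic form, by the orthogonality of the mixed coordinates.  To
    first order ds^2 equals twice the KL divergence between the laws at
    c and c + d.
    """
    dv = d.as_array()
    target = base_plus(c, d)  # validates feasibility of the step
    del target
    g = fisher_information(c).matrix
    return float(dv @ g @ dv)


def base_plus(c: Coordinates, d: TangentStep) -> Coordinates:
    """c + d as Coordinates; raises if the step leaves the manifold."""
    v = c.as_array() + d.as_array()
    try:
        out = Coordinates(*v)
        law_of(out)
    except ValueError as e:
        raise InfeasibleCoordinatesError(f"step leaves manifold: {e}") from e
    return out


def kl_divergence(p: JointLaw, q: JointLaw) -> float:
    """KL(p || q) by direct summation over the four outcomes."""
    pa, qa = p.as_array(), q.as_array()
    mask = pa > 0
    if np.any(qa[mask] <= 0):
        return math.inf
    return float(np.sum(pa[mask] * np.log(pa[mask] / qa[mask])))
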