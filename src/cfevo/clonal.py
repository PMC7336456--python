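"""Clonal deconvolution from longitudinal plasma mutation data.

Variant allele frequencies are normalized by tumor purity and local copy
number into cellular prevalences (the fraction of tumor cells carrying a
mutation). Mutations are clustered on their prevalence trajectories across
timepoints with a binomial-likelihood finite mixture (depth-weighted, K
chosen by BIC), a rooted clone tree is selected by exhaustive enumeration
with the lineage constraint that a parent's prevalence covers the sum of its
children's at every timepoint, and clones whose (disjoint) frequencies start
minor and expand over treatment are flagged as resistance-associated.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import EstimationUnavailable, InsufficientData, InvalidArgument, UnsupportedSize

logger = logging.getLogger(__name__)

__all__ = [
    "PrevalenceMatrix",
    "CloneModel",
    "ExpansionCall",
    "ClusterResult",
    "cellular_prevalence",
    "estimate_purity_simple",
    "build_prevalence_matrix",
    "cluster_mutations",
    "infer_tree",
    "clone_frequencies",
    "detect_expanding_clones",
    "infer_clonal_structure",
]

EPS_CONSTRAINT = 1e-6


def cellular_prevalence(
    vaf: float, purity: float, cn_total: int, multiplicity: int = 1
) -> float:
    """Fraction of tumor cells carrying a mutation.

    CP = vaf * (purity * cn_total + (1 - purity) * 2) / (purity * multiplicity),
    clipped to [0, 1] (clipping is logged). Normal cells contribute two copies.
    """
    if not 0 < purity <= 1:
        raise InvalidArgument("purity must be in (0, 1]")
    if cn_total < 1 or not 1 <= multiplicity <= cn_total:
        raise InvalidArgument("need cn_total >= 1 and 1 <= multiplicity <= cn_total")
    cp = vaf * (purity * cn_total + (1 - purity) * 2) / (purity * multiplicity)
    if cp > 1 or cp < 0:
        logger.debug("clipping cellular prevalence %.4f to [0, 1]", cp)
    return float(np.clip(cp, 0.0, 1.0))


def estimate_purity_simple(vafs, cn_per_site, quantile: float = 0.9) -> float:
    """Crude purity estimate from copy-neutral sites, used when none is supplied.

    Inverts the prevalence formula at CP = 1 for heterozygous clonal mutations
    on CN-2 sites: purity ~= 2 * upper-quantile of their VAFs (capped at 1).
    """
    vafs = np.asarray(vafs, dtype=float)
    cn = np.asarray(cn_per_site)
    if vafs.size < 5:
        raise InsufficientData("need >= 5 mutations to estimate purity")
    cn2 = vafs[cn == 2]
    if cn2.size == 0:
        raise EstimationUnavailable("no copy-neutral (CN 2) sites available")
    return float(min(1.0, 2.0 * np.quantile(cn2, quantile)))


@dataclass
class PrevalenceMatrix:
    """Mutations x timepoints cellular prevalences with their read-count backing.

    ``cp`` holds clipped prevalences; ``alt``/``depth`` the per-timepoint read
    counts the likelihood works on; ``cn``/``multiplicity`` are per-site,
    ``purity`` per-timepoint. ``excluded_keys`` lists mutations dropped before
    clustering (CN-0 sites, or prevalence inconsistent with [0, 1] beyond
    binomial noise).
    """

    keys: list
    cp: np.ndarray  # (N, T)
    alt: np.ndarray  # (N, T)
    depth: np.ndarray  # (N, T)
    purity: np.ndarray  # (T,)
    cn: np.ndarray  # (N,)
    multiplicity: np.ndarray  # (N,)
    excluded_keys: list = field(default_factory=list)

    @property
    def n_timepoints(self) -> int:
        return self.cp.shape[1]


def _vaf_coeff(purity: np.ndarray, cn: np.ndarray, mult: np.ndarray) -> np.ndarray:
    """c[i, t] such that expected VAF = c * prevalence."""
    return (purity[None, :] * mult[:, None]) / (
        purity[None, :] * cn[:, None] + (1 - purity[None, :]) * 2
    )


def build_prevalence_matrix(
    keys,
    alt: np.ndarray,
    depth: np.ndarray,
    purity,
    cn_per_site=None,
    multiplicity=None,
) -> PrevalenceMatrix:
    """Normalize per-timepoint VAFs into a prevalence matrix.

    Sites with CN 0, or whose prevalence exceeds 1 by more than three binomial
    standard errors at any timepoint (no valid prevalence can explain them),
    are excluded from clustering and reported; ordinary sampling noise above
    1 is clipped.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if alt.shape != depth.shape or alt.ndim != 2:
        raise InvalidArgument("alt and depth must be N x T arrays of equal shape")
    n, t = alt.shape
    purity = np.broadcast_to(np.asarray(purity, dtype=float), (t,)).copy()
    if np.any((purity <= 0) | (purity > 1)):
        raise InvalidArgument("purity values must be in (0, 1]")
    cn = (
        np.full(n, 2, dtype=int)
        if cn_per_site is None
        else np.asarray(cn_per_site, dtype=int)
    )
    mult = (
        np.ones(n, dtype=int) if multiplicity is None else np.asarray(multiplicity, dtype=int)
    )
    keep = cn >= 1
    vaf = np.divide(alt, depth, out=np.zeros_like(alt), where=depth > 0)
    coeff = _vaf_coeff(purity, np.maximum(cn, 1), mult)
    cp_raw = vaf / coeff
    se = np.sqrt(np.maximum(vaf * (1 - vaf), 1e-12) / np.maximum(depth, 1)) / coeff
    inconsistent = np.any(cp_raw > 1 + 3 * se, axis=1)
    keep &= ~inconsistent
    excluded = [k for k, ok in zip(keys, keep) if not ok]
    if excluded:
        logger.warning("excluding %d sites from clustering (CN 0 or CP >> 1)", len(excluded))
    kept = np.flatnonzero(keep)
    return PrevalenceMatrix(
        keys=[keys[i] for i in kept],
        cp=np.clip(cp_raw[kept], 0.0, 1.0),
        alt=alt[kept],
        depth=depth[kept],
        purity=purity,
        cn=cn[kept],
        multiplicity=mult[kept],
        excluded_keys=excluded,
    )


# ---------------------------------------------------------------------------
# mixture clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    assignment: np.ndarray  # (N,) cluster index
    centers: np.ndarray  # (K, T) cluster prevalences
    k: int
    loglik: float
    bic_by_k: dict


def _em_fit(alt, depth, coeff, k, rng, max_iter=200, tol=1e-6):
    n, t = alt.shape
    cp_hat = np.clip(
        np.divide(alt, depth, out=np.zeros_like(alt), where=depth > 0) / coeff, 0, 1
    )
    theta = cp_hat[rng.choice(n, size=k, replace=False)]
    pi = np.full(k, 1.0 / k)
    last = -np.inf
    resp = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        p = np.clip(coeff[:, None, :] * theta[None, :, :], 1e-9, 1 - 1e-9)  # (N, K, T)
        ll_ik = np.sum(
            alt[:, None, :] * np.log(p) + (depth - alt)[:, None, :] * np.log1p(-p), axis=2
        )
        logw = np.log(np.maximum(pi, 1e-300))[None, :] + ll_ik
        m = logw.max(axis=1, keepdims=True)
        loglik = float(np.sum(m.squeeze(1) + np.log(np.sum(np.exp(logw - m), axis=1))))
        resp = np.exp(logw - m)
        resp /= resp.sum(axis=1, keepdims=True)
        pi = resp.mean(axis=0)
        w = resp[:, :, None] * depth[:, None, :]  # depth-weighted responsibilities
        theta = np.clip(np.sum(w * cp_hat[:, None, :], axis=0) / np.maximum(np.sum(w, axis=0), 1e-12), 0, 1)
        if abs(loglik - last) < tol:
            break
        last = loglik
    return loglik, theta, pi, resp


def cluster_mutations(
    prev: PrevalenceMatrix, k_max: int = 8, seed: int = 0, n_restarts: int = 20
) -> ClusterResult:
    """Cluster mutations on prevalence trajectories; K chosen by BIC over 1..k_max.

    The mixture uses binomial likelihoods on alt/depth counts (low-depth sites
    carry less weight) with cluster-specific per-timepoint prevalences;
    seeded multi-restart EM per K.
    """
    n = len(prev.keys)
    if n < 1:
        raise InvalidArgument("no mutations to cluster")
    if k_max < 1 or k_max > 8:
        raise InvalidArgument("k_max must be in 1..8")
    rng = np.random.default_rng(seed)
    coeff = _vaf_coeff(prev.purity, np.maximum(prev.cn, 1), prev.multiplicity)
    t = prev.n_timepoints
    best = None
    bic_by_k = {}
    for k in range(1, min(k_max, n) + 1):
        k_best = None
        for _ in range(n_restarts):
            ll, theta, pi, resp = _em_fit(prev.alt, prev.depth, coeff, k, rng)
            if k_best is None or ll > k_best[0]:
                k_best = (ll, theta, pi, resp)
        ll, theta, pi, resp = k_best
        n_params = k * t + (k - 1)
        bic = -2 * ll + n_params * np.log(n * t)
        bic_by_k[k] = bic
        if best is None or bic < best[0]:
            best = (bic, k, ll, theta, resp)
    _, k, ll, theta, resp = best
    assignment = np.argmax(resp, axis=1)
    # drop empty clusters so centers describe occupied clones only
    used = np.unique(assignment)
    remap = {int(c): i for i, c in enumerate(used)}
    assignment = np.array([remap[int(c)] for c in assignment])
    theta = theta[used]
    return ClusterResult(
        assignment=assignment, centers=theta, k=len(used), loglik=ll, bic_by_k=bic_by_k
    )


# ---------------------------------------------------------------------------
# clone tree inference
# ---------------------------------------------------------------------------


@dataclass
class CloneModel:
    """Clone clusters with a rooted tree and feasible prevalences.

    ``parent`` maps clone index -> parent index, -1 meaning a child of the
    implicit root (whose prevalence is bounded by 1). ``clone_prevalence`` is
    the projected K x T lineage-prevalence matrix satisfying
    parent >= sum(children) at every timepoint.
    """

    k: int
    parent: tuple
    clone_prevalence: np.ndarray  # (K, T)
    fit_error: float
    assignment: np.ndarray | None = None
    keys: list | None = None

    def children(self, c: int) -> list[int]:
        return [i for i, p in enumerate(self.parent) if p == c]

    def validate(self, eps: float = EPS_CONSTRAINT):
        prev = self.clone_prevalence
        for c in range(self.k):
            ch = self.children(c)
            if ch and np.any(prev[c] < prev[ch].sum(axis=0) - eps):
                raise InvalidArgument("clone model violates the lineage sum constraint")
        top = [i for i, p in enumerate(self.parent) if p == -1]
        if np.any(prev[top].sum(axis=0) > 1 + eps):
            raise InvalidArgument("top-level prevalences exceed 1")


def _enumerate_parent_maps(k: int):
    """All rooted forests on k labeled clones under an implicit root (-1)."""
    for combo in itertools.product(*[[-1] + [j for j in range(k) if j != i] for i in range(k)]):
        ok = True
        for i in range(k):
            seen = {i}
            p = combo[i]
            while p != -1:
                if p in seen:
                    ok = False
                    break
                seen.add(p)
                p = combo[p]
            if not ok:
                break
        if ok:
            yield combo


def _feasible(parent, x: np.ndarray, eps: float = EPS_CONSTRAINT) -> bool:
    k = len(parent)
    sums = np.zeros_like(x)
    top = np.zeros(x.shape[1])
    for i in range(k):
        if parent[i] == -1:
            top += x[i]
        else:
            sums[parent[i]] += x[i]
    return bool(np.all(x >= sums - eps) and np.all(top <= 1 + eps))


def _project_timepoint(parent, c: np.ndarray) -> tuple[np.ndarray, float]:
    """Project one timepoint's centers onto the feasible cone of a tree."""
    k = len(parent)
    cons = []
    for i in range(k):
        ch = [j for j in range(k) if parent[j] == i]
        if ch:
            cons.append({"type": "ineq", "fun": lambda x, i=i, ch=tuple(ch): x[i] - sum(x[j] for j in ch)})
    top = [i for i in range(k) if parent[i] == -1]
    cons.append({"type": "ineq", "fun": lambda x, top=tuple(top): 1.0 - sum(x[j] for j in top)})
    res = minimize(
        lambda x: np.sum((x - c) ** 2),
        np.clip(c, 0, 1),
        jac=lambda x: 2 * (x - c),
        bounds=[(0.0, 1.0)] * k,
        constraints=cons,
        method="SLSQP",
    )
    x = np.clip(res.x, 0, 1)
    return x, float(np.sum((x - c) ** 2))


def infer_tree(centers: np.ndarray, max_enumeration: int = 6) -> CloneModel:
    """Best rooted clone tree by exhaustive enumeration.

    Every parent map over the K clusters (with an implicit root bounding the
    top-level prevalences by 1) is scored by projecting the cluster centers
    onto the tree's feasible set per timepoint (non-negative least squares
    under the lineage sum constraints); the minimum squared projection error
    wins. Ties prefer the most linear topology (fewest branches out of any
    clone, i.e. maximal total depth), then the lexically smallest parent map:
    a chain of prevalences 0.9 >= 0.5 >= 0.2 is reported as a chain even
    though a star under the top clone is also feasible, because nesting makes
    the strictest constraints that the data still satisfies. K above
    ``max_enumeration`` raises UnsupportedSize.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    k, t = centers.shape
    if k > max_enumeration:
        raise UnsupportedSize(
            f"{k} clones exceeds the enumeration bound {max_enumeration}; "
            "raise max_enumeration explicitly to proceed"
        )
    best = None
    for parent in _enumerate_parent_maps(k):
        if _feasible(parent, centers):
            err, proj = 0.0, centers.copy()
        else:
            proj = np.empty_like(centers)
            err = 0.0
            for tt in range(t):
                proj[:, tt], e = _project_timepoint(parent, centers[:, tt])
                err += e
        depth_sum = 0
        for i in range(k):
            p = parent[i]
            while p != -1:
                depth_sum += 1
                p = parent[p]
        key = (round(err, 12), -depth_sum, parent)
        if best is None or key < best[0]:
            best = (key, parent, proj, err)
    _, parent, proj, err = best
    model = CloneModel(k=k, parent=tuple(parent), clone_prevalence=proj, fit_error=err)
    model.validate(eps=1e-4)
    return model


def clone_frequencies(model: CloneModel) -> np.ndarray:
    """Disjoint clone frequencies: own prevalence minus the children's sum.

    Small negative values from numerical projection are clipped at 0; the
    per-timepoint total never exceeds 1 (up to the constraint tolerance).
    """
    prev = model.clone_prevalence
    freq = prev.copy()
    for c in range(model.k):
        ch = model.children(c)
        if ch:
            freq[c] = prev[c] - prev[ch].sum(axis=0)
    return np.clip(freq, 0.0, 1.0)


@dataclass(frozen=True)
class ExpansionCall:
    clone_id: int
    initial_frequency: float
    final_frequency: float
    flagged: bool
    mutations_carried: tuple
    significant_mutations: tuple


def detect_expanding_clones(
    model: CloneModel,
    minor_max: float = 0.21,
    expansion_min: float = 0.20,
    functional_flags: dict | None = None,
) -> list[ExpansionCall]:
    """Flag minor clones that expanded over the sampled timepoints.

    A clone is flagged when its first-timepoint frequency is at most
    ``minor_max`` (minor subclones occupy 1-21% of the tumor) and its final
    minus first frequency reaches ``expansion_min``. ``functional_flags``
    maps mutation keys to a functional-significance boolean; flagged clones
    report the significant mutations they carry.
    """
    freq = clone_frequencies(model)
    if freq.shape[1] < 2:
        raise InvalidArgument("need >= 2 timepoints to detect expansion")
    out = []
    for c in range(model.k):
        first, last = float(freq[c, 0]), float(freq[c, -1])
        flagged = first <= minor_max and (last - first) >= expansion_min
        muts = tuple(
            k for k, a in zip(model.keys or [], model.assignment if model.assignment is not None else [])
            if a == c
        )
        sig = tuple(m for m in muts if functional_flags and functional_flags.get(m))
        out.append(
            ExpansionCall(
                clone_id=c,
                initial_frequency=first,
                final_frequency=last,
                flagged=flagged,
                mutations_carried=muts,
                significant_mutations=sig,
            )
        )
    return out


def infer_clonal_structure(
    prev: PrevalenceMatrix, k_max: int = 8, seed: int = 0, max_enumeration: int = 6
) -> CloneModel:
    """Cluster mutations, infer the clone tree, and attach assignments."""
    clusters = cluster_mutations(prev, k_max=k_max, seed=seed)
    model = infer_tree(clusters.centers, max_enumeration=max_enumeration)
    model.assignment = clusters.assignment
    model.keys = prev.keys
    return model
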