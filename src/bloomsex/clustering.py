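"""Model-based NB mixture clustering of temporal expression profiles.

Genes are clustered by the *shape* of their expression over conditions
(days): within cluster k, counts follow
``x_gj ~ NB(mean s_j * q_g * 2**p_kj, shape 1/alpha)`` where the
gene-specific abundance q_g is profiled out at its (Poisson-score) MLE,
so the cluster parameter p_k is a row-centered vector of condition
effects on the log2 scale — the log2FC curve of the cluster. Fitting is
EM with k-means initialization on log2FC-over-median profiles; the
M-step improves (never decreases) the expected complete-data
log-likelihood via bounded quasi-Newton steps, so the observed
log-likelihood is non-decreasing across iterations (generalized EM).
Clusters with near-identical profiles can be merged afterwards.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln, logsumexp

from .expression import log2fc_over_median

LN2 = np.log(2.0)
_ALPHA_BOUNDS = (np.log(1e-6), np.log(10.0))


def _ll_const(x: np.ndarray, alpha: float) -> np.ndarray:
    """Per-gene sum of the profile-independent NB log-pmf terms."""
    r = 1.0 / max(alpha, 1e-12)
    return (gammaln(x + r) - gammaln(r) - gammaln(x + 1.0)).sum(axis=1)


def _mu_profiled(x, s, p_k, xsum):
    """Mean matrix under profile p_k with abundance q profiled out."""
    se = s * np.exp2(p_k)
    q = np.maximum(xsum / se.sum(), 1e-12)
    return np.maximum(q[:, None] * se[None, :], 1e-300)


def _ll_core(x, mu, alpha) -> np.ndarray:
    """Per-gene profile-dependent NB log-pmf terms (no gammaln constants)."""
    r = 1.0 / max(alpha, 1e-12)
    return (r * np.log(r / (r + mu)) + x * np.log(mu / (r + mu))).sum(axis=1)


def _profiled_loglik(x, s, p_k, alpha, xsum):
    """Per-gene NB loglik under profile p_k with abundance q profiled out."""
    return _ll_core(x, _mu_profiled(x, s, p_k, xsum), alpha) + _ll_const(x, alpha)


class ProfileMixture:
    """NB mixture model over per-day pooled counts of DE genes.

    Parameters
    ----------
    counts
        Pooled genes x conditions count DataFrame (replicates summed).
    size_factors
        Positive per-condition size factors.
    n_clusters
        Number of mixture components K.
    n_starts
        Independent k-means initializations; the best final likelihood
        wins.
    tol, max_iter
        EM stopping rule: relative log-likelihood change below ``tol``
        or ``max_iter`` iterations.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        size_factors: pd.Series,
        n_clusters: int,
        n_starts: int = 5,
        tol: float = 1e-6,
        max_iter: int = 500,
    ):
        if n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if n_clusters > counts.shape[0]:
            raise ValueError(f"K={n_clusters} exceeds number of genes ({counts.shape[0]})")
        self.counts = counts
        self.size_factors = size_factors.reindex(counts.columns)
        self.K = n_clusters
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter

    # -- internals ---------------------------------------------------------

    def _init_profiles(self, seed: int) -> tuple[np.ndarray, np.ndarray]:
        from sklearn.cluster import KMeans

        lfc = log2fc_over_median(self.counts, self.size_factors).to_numpy()
        lfc = lfc - lfc.mean(axis=1, keepdims=True)
        km = KMeans(n_clusters=self.K, n_init=1, random_state=seed)
        labels = km.fit_predict(lfc)
        profiles = np.zeros((self.K, self.counts.shape[1]))
        for k in range(self.K):
            sel = labels == k
            profiles[k] = lfc[sel].mean(axis=0) if sel.any() else lfc[np.random.default_rng(seed + k).integers(len(lfc))]
        pi = np.bincount(labels, minlength=self.K).astype(float)
        pi = np.maximum(pi, 1.0)
        return profiles - profiles.mean(axis=1, keepdims=True), pi / pi.sum()

    def _loglik_by_cluster(self, x, s, xsum, profiles, alpha) -> np.ndarray:
        const = _ll_const(x, alpha)
        return np.column_stack(
            [_ll_core(x, _mu_profiled(x, s, profiles[k], xsum), alpha) + const for k in range(self.K)]
        )

    def _em(self, seed: int) -> dict:
        x = self.counts.to_numpy(float)
        s = self.size_factors.to_numpy(float)
        xsum = x.sum(axis=1)
        profiles, pi = self._init_profiles(seed)
        alpha = 0.2
        path = []
        ll_obs = -np.inf
        for _ in range(self.max_iter):
            llk = self._loglik_by_cluster(x, s, xsum, profiles, alpha)
            logw = np.log(pi)[None, :] + llk
            ll_new = float(logsumexp(logw, axis=1).sum())
            path.append(ll_new)
            resp = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))

            converged = np.isfinite(ll_obs) and abs(ll_new - ll_obs) <= self.tol * (abs(ll_obs) + 1.0)
            ll_obs = ll_new
            if converged:
                break

            # M-step (generalized: each block move never decreases its objective)
            pi = np.maximum(resp.mean(axis=0), 1e-12)
            pi = pi / pi.sum()
            for k in range(self.K):
                profiles[k] = self._update_profile(x, s, xsum, profiles[k], resp[:, k], alpha)
            alpha = self._update_alpha(x, s, xsum, profiles, resp, alpha)

        llk = self._loglik_by_cluster(x, s, xsum, profiles, alpha)
        logw = np.log(pi)[None, :] + llk
        resp = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
        return {
            "profiles": profiles,
            "pi": pi,
            "alpha": alpha,
            "resp": resp,
            "loglik": ll_obs,
            "loglik_path": path,
        }

    def _update_profile(self, x, s, xsum, p_k, r_k, alpha) -> np.ndarray:
        if r_k.sum() < 1e-8:
            return p_k
        r_shape = 1.0 / max(alpha, 1e-12)

        def neg_q_and_grad(p):
            se = s * np.exp2(p)
            denom = se.sum()
            q = np.maximum(xsum / denom, 1e-12)
            mu = np.maximum(q[:, None] * se[None, :], 1e-300)
            core = (r_shape * np.log(r_shape / (r_shape + mu)) + x * np.log(mu / (r_shape + mu))).sum(axis=1)
            # d ll / d p_m  =  ln2 * (A_gm - w_m * sum_j A_gj), A = r(x-mu)/(r+mu)
            A = r_shape * (x - mu) / (r_shape + mu)
            w = se / denom
            t1 = r_k @ A
            grad = -LN2 * (t1 - w * t1.sum())
            return -float(np.dot(r_k, core)), grad

        f0, _ = neg_q_and_grad(p_k)
        res = minimize(neg_q_and_grad, p_k, jac=True, method="L-BFGS-B", options={"maxiter": 25})
        p_new = res.x if res.fun <= f0 else p_k
        return p_new - p_new.mean()

    def _update_alpha(self, x, s, xsum, profiles, resp, alpha) -> float:
        mus = [_mu_profiled(x, s, profiles[k], xsum) for k in range(self.K)]

        def neg_q(log_a):
            a = float(np.exp(log_a))
            const = _ll_const(x, a)
            total = 0.0
            for k in range(self.K):
                total += float(resp[:, k] @ (_ll_core(x, mus[k], a) + const))
            return -total

        f0 = neg_q(np.log(alpha))
        res = minimize_scalar(neg_q, bounds=_ALPHA_BOUNDS, method="bounded", options={"xatol": 1e-3})
        return float(np.exp(res.x)) if res.fun <= f0 else alpha

    # -- public API --------------------------------------------------------

    def fit(self, seed: int = 0) -> "ProfileMixtureResults":
        """Run EM from ``n_starts`` k-means initializations; keep the best."""
        best = None
        for i in range(self.n_starts):
            out = self._em(seed=seed * 1009 + i)
            if best is None or out["loglik"] > best["loglik"]:
                best = out
        return ProfileMixtureResults(self, best)


class ProfileMixtureResults:
    """Fitted NB profile mixture: profiles, weights, responsibilities."""

    def __init__(self, model: ProfileMixture, state: dict):
        self.model = model
        self.profiles = pd.DataFrame(
            state["profiles"], index=range(1, model.K + 1), columns=model.counts.columns
        )
        self.pi = pd.Series(state["pi"], index=self.profiles.index, name="pi")
        self.alpha = float(state["alpha"])
        self.responsibilities = pd.DataFrame(
            state["resp"], index=model.counts.index, columns=self.profiles.index
        )
        self.loglik = float(state["loglik"])
        self.loglik_path = list(state["loglik_path"])

    @property
    def K(self) -> int:
        return self.profiles.shape[0]

    @property
    def assignments(self) -> pd.Series:
        """Hard assignment: argmax responsibility, ties to lowest index."""
        r = self.responsibilities.to_numpy()
        hard = self.responsibilities.columns.to_numpy()[r.argmax(axis=1)]
        return pd.Series(hard, index=self.responsibilities.index, name="cluster")

    @property
    def n_parameters(self) -> int:
        # K row-centered profiles, K-1 free weights, one shared dispersion
        J = self.profiles.shape[1]
        return self.K * (J - 1) + (self.K - 1) + 1

    def bic(self) -> float:
        n = self.model.counts.size
        return -2.0 * self.loglik + self.n_parameters * np.log(n)

    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().reindex(self.profiles.index, fill_value=0)

    def merge_similar(self, r_min: float = 0.9) -> "ProfileMixtureResults":
        """Iteratively merge the profile pair with the highest Pearson
        correlation while it exceeds ``r_min`` (ties: smallest indices).

        The merged profile is refit by one weighted M-step on the summed
        responsibilities; labels are renumbered 1..K' preserving order.
        """
        x = self.model.counts.to_numpy(float)
        s = self.model.size_factors.to_numpy(float)
        xsum = x.sum(axis=1)
        profiles = self.profiles.to_numpy().copy()
        resp = self.responsibilities.to_numpy().copy()
        pi = self.pi.to_numpy().copy()

        while profiles.shape[0] > 1:
            K = profiles.shape[0]
            corr = np.corrcoef(profiles)
            np.fill_diagonal(corr, -np.inf)
            best, pair = -np.inf, None
            for i in range(K):
                for j in range(i + 1, K):
                    if corr[i, j] > best + 1e-12:
                        best, pair = corr[i, j], (i, j)
            if best <= r_min:
                break
            i, j = pair
            r_merged = resp[:, i] + resp[:, j]
            p0 = (pi[i] * profiles[i] + pi[j] * profiles[j]) / (pi[i] + pi[j])
            p_new = self.model._update_profile(x, s, xsum, p0, r_merged, self.alpha)
            profiles = np.vstack([profiles[:i], [p_new], profiles[i + 1 : j], profiles[j + 1 :]])
            resp = np.column_stack([resp[:, :i], r_merged, resp[:, i + 1 : j], resp[:, j + 1 :]])
            pi = np.concatenate([pi[:i], [pi[i] + pi[j]], pi[i + 1 : j], pi[j + 1 :]])

        llk = np.column_stack(
            [_profiled_loglik(x, s, profiles[k], self.alpha, xsum) for k in range(profiles.shape[0])]
        )
        logw = np.log(pi)[None, :] + llk
        resp_new = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
        ll = float(logsumexp(logw, axis=1).sum())
        model = ProfileMixture(
            self.model.counts,
            self.model.size_factors,
            profiles.shape[0],
            n_starts=self.model.n_starts,
            tol=self.model.tol,
            max_iter=self.model.max_iter,
        )
        state = {
            "profiles": profiles,
            "pi": pi,
            "alpha": self.alpha,
            "resp": resp_new,
            "loglik": ll,
            "loglik_path": self.loglik_path + [ll],
        }
        return ProfileMixtureResults(model, state)

    def summary(self) -> str:
        sizes = self.cluster_sizes()
        lines = [
            "NB profile mixture",
            f"K = {self.K}, genes = {self.model.counts.shape[0]}, "
            f"conditions = {self.model.counts.shape[1]}",
            f"dispersion alpha = {self.alpha:.4f}, log-likelihood = {self.loglik:.2f}, "
            f"BIC = {self.bic():.2f}",
        ]
        for k in self.profiles.index:
            peak = self.profiles.loc[k].idxmax()
            lines.append(
                f"  cluster {k}: {int(sizes[k])} genes, pi={self.pi[k]:.3f}, peak day {peak}"
            )
        return "\n".join(lines)


def em_cluster(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    n_clusters: int,
    seed: int = 0,
    **kw,
) -> ProfileMixtureResults:
    """Functional wrapper: fit the NB profile mixture."""
    return ProfileMixture(counts, size_factors, n_clusters, **kw).fit(seed=seed)


def merge_similar(result: ProfileMixtureResults, r_min: float = 0.9) -> ProfileMixtureResults:
    return result.merge_similar(r_min=r_min)


def choose_k(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    k_grid,
    seed: int = 0,
    **kw,
) -> tuple[int, pd.Series]:
    """Pick K by BIC over ``k_grid``; returns (K, BIC curve)."""
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    bics = {}
    for k in k_grid:
        bics[k] = em_cluster(counts, size_factors, k, seed=seed, **kw).bic()
    curve = pd.Series(bics, name="bic")
    return int(curve.idxmin()), curve
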