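"""Nearest shrunken centroid classification for categorical SNP genotypes.

The classical nearest-shrunken-centroid classifier works on continuous
features: per-class means are shrunk toward the overall mean by soft
thresholding a standardized distance, which zeroes uninformative features.
SNP genotypes are categorical (AA / Aa / aa, optionally missing), so this
module replaces means with genotype *distribution vectors*: the per-class
centroid of SNP i is its within-class category frequency vector f_ik, the
overall centroid is the pooled frequency vector f_i, and the per-class
distance statistic is

    d_ik = ||f_ik - f_i||_2 / (m_k * (s_i + s0))

with m_k = sqrt(1/n_k - 1/n), s_i the pooled within-class dispersion of
one-hot genotype indicators,

    s_i^2 = (1 / (n - K)) * sum_k sum_{j in C_k} ||e(x_ij) - f_ik||_2^2,

and s0 a guard (by default the median of the s_i).  Soft thresholding
d'_ik = max(d_ik - Delta, 0) shrinks each class distribution toward the
overall one, f'_ik = f_i + (f_ik - f_i) * d'_ik / d_ik, and a SNP is
*selected* when any class retains d'_ik > 0.  A test sample t is assigned
to the class minimizing the discriminant score

    delta_k(t) = sum_i ||e(t_i) - f'_ik||_2^2 / (s_i + s0)^2 - 2 log pi_k.

`NumericShrunkenCentroid` provides the classical numeric-coding baseline
(missing=0, AA=1, Aa=2, aa=3) with the same fit/predict/select API.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np

from .io import CATEGORIES, MISSING, GenotypeMatrix


def soft_threshold(d, delta):
    """Soft thresholding map d -> max(d - delta, 0) for nonnegative inputs."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("soft_threshold requires d >= 0")
    if delta < 0:
        raise ValueError("soft_threshold requires delta >= 0")
    out = np.maximum(d - delta, 0.0)
    return float(out) if out.ndim == 0 else out


class ShrunkenCentroid:
    """Categorical nearest-shrunken-centroid model for a genotype matrix.

    Parameters
    ----------
    genotypes
        Labeled :class:`~snpshrink.io.GenotypeMatrix`.
    include_missing
        When True (default) missing is a 4th genotype category entering
        every distribution vector.  When False distributions run over
        (AA, Aa, aa) with missing calls excluded from denominators.
    priors
        "empirical" (class proportions n_k/n), "uniform", or an explicit
        array over the sorted class labels.
    s0
        "median" for the median of the per-SNP dispersions, or a fixed
        nonnegative float.
    m_rule
        "subtract" for m_k = sqrt(1/n_k - 1/n) (default) or "add" for
        sqrt(1/n_k + 1/n).

    Calling :meth:`fit` with a shrinkage amount ``delta`` returns a
    :class:`ShrunkenCentroidResults`.
    """

    def __init__(self, genotypes: GenotypeMatrix, *, include_missing: bool = True,
                 priors="empirical", s0="median", m_rule: str = "subtract"):
        if genotypes.labels is None:
            raise ValueError("genotype matrix must carry class labels")
        self.genotypes = genotypes
        self.include_missing = include_missing
        self.class_labels = genotypes.classes()
        self.K = len(self.class_labels)
        if self.K < 2:
            raise ValueError("need at least 2 classes")
        self.n, self.p = genotypes.calls.shape
        self.n_categories = 4 if include_missing else 3
        self.m_rule = m_rule
        self._label_index = {lab: k for k, lab in enumerate(self.class_labels)}
        self.y = np.array([self._label_index[l] for l in genotypes.labels])
        self.n_k = np.bincount(self.y, minlength=self.K).astype(float)
        if np.any(self.n_k == 0):
            raise ValueError("empty class")

        if isinstance(priors, str):
            if priors == "empirical":
                self.priors = self.n_k / self.n
            elif priors == "uniform":
                self.priors = np.full(self.K, 1.0 / self.K)
            else:
                raise ValueError(f"unknown priors rule {priors!r}")
        else:
            self.priors = np.asarray(priors, dtype=float)
            if self.priors.shape != (self.K,) or not np.isclose(self.priors.sum(), 1):
                raise ValueError("explicit priors must sum to 1 over K classes")

        self._fit_base(s0)

    # -- base (unshrunken) centroid statistics ---------------------------

    def _fit_base(self, s0_rule) -> None:
        calls = self.genotypes.calls
        C = self.n_categories
        onehot = np.zeros((self.n, self.p, 4))
        np.put_along_axis(onehot, calls[:, :, None].astype(int), 1.0, axis=2)
        if not self.include_missing:
            onehot = onehot[:, :, :3]  # missing rows contribute nothing

        # class_counts[k, i, c]: genotype category counts within class k
        class_counts = np.stack([onehot[self.y == k].sum(axis=0)
                                 for k in range(self.K)])
        overall_counts = class_counts.sum(axis=0)
        if self.include_missing:
            class_denom = self.n_k[:, None, None]
            overall_denom = float(self.n)
        else:
            class_denom = class_counts.sum(axis=2, keepdims=True)
            overall_denom = overall_counts.sum(axis=1, keepdims=True)
            if np.any(class_denom == 0):
                raise ValueError(
                    "a SNP is entirely missing within a class; cannot form "
                    "3-category distributions (use include_missing=True)"
                )
        # f_ik and f_i, stored (K, p, C) and (p, C)
        self.class_dists = class_counts / class_denom
        self.overall_dists = overall_counts / overall_denom
        self.class_modes = np.argmax(self.class_dists, axis=2)  # ties: first wins
        self.overall_modes = np.argmax(self.overall_dists, axis=1)

        # pooled within-class dispersion of one-hot indicators:
        # sum_{j in C_k} ||e(x_ij) - f_ik||^2 = n_k_eff * (1 - ||f_ik||^2)
        sq = np.sum(self.class_dists**2, axis=2)  # (K, p)
        n_eff = np.broadcast_to(class_denom[..., 0], sq.shape)
        ss = (n_eff * (1.0 - sq)).sum(axis=0)  # (p,)
        denom = (n_eff.sum(axis=0) - self.K) if not self.include_missing \
            else float(self.n - self.K)
        self.s = np.sqrt(np.maximum(ss, 0.0) / np.maximum(denom, 1.0))

        if s0_rule == "median":
            self.s0 = float(np.median(self.s))
            if self.s0 == 0:
                # degenerate panels (most SNPs class-constant): keep the
                # guard positive so distances and scores stay finite
                pos = self.s[self.s > 0]
                self.s0 = float(pos.min()) if pos.size else 1.0
        else:
            self.s0 = float(s0_rule)
            if self.s0 < 0:
                raise ValueError("fixed s0 must be nonnegative")
        if self.s0 == 0 and np.any(self.s == 0):
            warnings.warn("s0 is 0 and some SNPs have zero dispersion")

        if self.m_rule == "subtract":
            self.m_k = np.sqrt(1.0 / self.n_k - 1.0 / self.n)
        elif self.m_rule == "add":
            self.m_k = np.sqrt(1.0 / self.n_k + 1.0 / self.n)
        else:
            raise ValueError(f"unknown m_rule {self.m_rule!r}")

        diff = self.class_dists - self.overall_dists[None]
        norm = np.sqrt(np.sum(diff**2, axis=2))  # (K, p)
        scale = self.m_k[:, None] * (self.s + self.s0)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(scale > 0, norm / scale, 0.0)
        self.d = d.T  # (p, K)

    def fit(self, delta: float = 0.0) -> "ShrunkenCentroidResults":
        """Apply shrinkage amount ``delta`` and return results."""
        if delta < 0:
            raise ValueError("delta must be >= 0")
        d_shrunk = soft_threshold(self.d, delta)  # (p, K)
        ratio = np.zeros_like(self.d)
        nz = self.d > 0
        ratio[nz] = d_shrunk[nz] / self.d[nz]
        # f'_ik = f_i + (f_ik - f_i) * d'/d  -- convex combination
        shrunk = (self.overall_dists[None]
                  + (self.class_dists - self.overall_dists[None])
                  * ratio.T[:, :, None])
        # unshrunk entries (ratio 1) reproduce f_ik exactly
        shrunk = np.where(ratio.T[:, :, None] == 1.0, self.class_dists, shrunk)
        return ShrunkenCentroidResults(self, float(delta), d_shrunk, shrunk)


@dataclasses.dataclass
class ShrunkenCentroidResults:
    """Fitted shrunken model at one value of the shrinkage amount Delta."""

    model: ShrunkenCentroid
    delta: float
    d_shrunk: np.ndarray       # (p, K)
    shrunk_dists: np.ndarray   # (K, p, C)

    @property
    def selected(self) -> np.ndarray:
        """Indices of SNPs with max_k d'_ik > 0, in SNP order."""
        return np.flatnonzero(self.d_shrunk.max(axis=1) > 0)

    def selected_snps(self) -> list[tuple[str, np.ndarray]]:
        """Selected (snp_id, per-class d'_ik), sorted by max d' descending.

        Ties keep SNP-index order.
        """
        idx = self.selected
        order = sorted(idx, key=lambda i: (-self.d_shrunk[i].max(), i))
        ids = self.model.genotypes.snp_ids
        return [(ids[i], self.d_shrunk[i].copy()) for i in order]

    def _scores_matrix(self, calls: np.ndarray, use_shrunken: bool) -> np.ndarray:
        m = self.model
        centroids = self.shrunk_dists if use_shrunken else m.class_dists
        snp_idx = np.arange(m.p) if use_shrunken else self.selected
        if not use_shrunken and snp_idx.size == 0:
            snp_idx = np.arange(m.p)  # nothing selected: fall back to all
        w = 1.0 / (m.s + m.s0) ** 2  # (p,)
        calls = np.asarray(calls)
        if calls.ndim == 1:
            calls = calls[None, :]
        if calls.shape[1] != m.p:
            raise ValueError(f"expected {m.p} SNPs, got {calls.shape[1]}")
        if calls.max(initial=0) > 3 or calls.min(initial=0) < 0:
            raise ValueError("calls contain codes outside the category set")
        if not m.include_missing and np.any(calls == MISSING):
            # 3-category model: missing test calls contribute nothing
            obs = calls != MISSING
        else:
            obs = np.ones_like(calls, dtype=bool)
        scores = np.empty((calls.shape[0], m.K))
        for k in range(m.K):
            F = centroids[k]                       # (p, C)
            q = 1.0 + np.sum(F**2, axis=1)         # (p,) = ||e||^2 + ||f||^2
            fx = np.zeros(calls.shape)
            valid = obs & (calls < F.shape[1])
            rows, cols = np.nonzero(valid)
            fx[rows, cols] = F[cols, calls[rows, cols]]
            per_snp = (q[None, :] - 2.0 * fx) * w[None, :]
            per_snp = np.where(obs, per_snp, 0.0)
            scores[:, k] = per_snp[:, snp_idx].sum(axis=1)
        return scores - 2.0 * np.log(m.priors)[None, :]

    def predict_scores(self, data, use_shrunken: bool = True) -> np.ndarray:
        """Per-class discriminant scores delta_k(t); lower is closer."""
        calls = data.calls if isinstance(data, GenotypeMatrix) else data
        return self._scores_matrix(np.asarray(calls), use_shrunken)

    def predict(self, data, use_shrunken: bool = True) -> np.ndarray:
        """Class labels by minimum score; ties -> larger prior, then lower
        class index."""
        scores = self.predict_scores(data, use_shrunken)
        m = self.model
        labels = []
        for row in scores:
            cand = np.flatnonzero(row == row.min())
            k = min(cand, key=lambda c: (-m.priors[c], c))
            labels.append(m.class_labels[k])
        return np.array(labels, dtype=object)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Categorical nearest shrunken centroid",
            "=" * 45,
            f"samples: {m.n}    SNPs: {m.p}    classes: {m.K}",
            f"categories: {'AA/Aa/aa/missing' if m.include_missing else 'AA/Aa/aa'}",
            f"delta: {self.delta:g}    s0: {m.s0:.6g}",
            f"priors: " + ", ".join(
                f"{lab}={pi:.3f}" for lab, pi in zip(m.class_labels, m.priors)),
            f"SNPs selected: {len(self.selected)} / {m.p}",
        ]
        top = self.selected_snps()[:10]
        if top:
            lines.append("top SNPs (max_k d'_ik):")
            for sid, dvec in top:
                lines.append(f"  {sid:<15s} {dvec.max():.4f}")
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------

    def to_json(self, path=None) -> str:
        m = self.model
        obj = {
            "delta": self.delta,
            "class_labels": [str(l) for l in m.class_labels],
            "categories": list(CATEGORIES[: m.n_categories]),
            "priors": m.priors.tolist(),
            "s": m.s.tolist(),
            "s0": m.s0,
            "snp_ids": m.genotypes.snp_ids,
            "class_dists": m.class_dists.tolist(),
            "overall_dists": m.overall_dists.tolist(),
            "d": m.d.tolist(),
            "d_shrunk": self.d_shrunk.tolist(),
            "shrunk_dists": self.shrunk_dists.tolist(),
            "selected_snp_ids": [sid for sid, _ in self.selected_snps()],
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class NumericShrunkenCentroid:
    """Classical nearest shrunken centroid on numeric genotype codes.

    Genotypes are recoded missing=0, AA=1, Aa=2, aa=3 and treated as
    continuous, exactly the numeric-representation baseline: per-class
    means, pooled within-class standard deviation, a t-like standardized
    difference soft-thresholded in absolute value, and a squared-distance
    discriminant with the same prior term as the categorical model.
    """

    _RECODE = np.array([1.0, 2.0, 3.0, 0.0])  # AA, Aa, aa, missing

    def __init__(self, genotypes: GenotypeMatrix, *, priors="empirical",
                 s0="median", m_rule: str = "subtract"):
        if genotypes.labels is None:
            raise ValueError("genotype matrix must carry class labels")
        self.genotypes = genotypes
        self.class_labels = genotypes.classes()
        self.K = len(self.class_labels)
        self.n, self.p = genotypes.calls.shape
        self._label_index = {lab: k for k, lab in enumerate(self.class_labels)}
        self.y = np.array([self._label_index[l] for l in genotypes.labels])
        self.n_k = np.bincount(self.y, minlength=self.K).astype(float)
        if np.any(self.n_k == 0):
            raise ValueError("empty class")
        if priors == "empirical":
            self.priors = self.n_k / self.n
        elif priors == "uniform":
            self.priors = np.full(self.K, 1.0 / self.K)
        else:
            self.priors = np.asarray(priors, dtype=float)

        x = self._RECODE[genotypes.calls.astype(int)]  # (n, p)
        self.class_means = np.stack([x[self.y == k].mean(axis=0)
                                     for k in range(self.K)])  # (K, p)
        self.overall_means = x.mean(axis=0)
        ss = np.zeros(self.p)
        for k in range(self.K):
            ss += ((x[self.y == k] - self.class_means[k]) ** 2).sum(axis=0)
        self.s = np.sqrt(ss / (self.n - self.K))
        self.s0 = float(np.median(self.s)) if s0 == "median" else float(s0)
        if m_rule == "subtract":
            self.m_k = np.sqrt(1.0 / self.n_k - 1.0 / self.n)
        else:
            self.m_k = np.sqrt(1.0 / self.n_k + 1.0 / self.n)
        scale = self.m_k[:, None] * (self.s + self.s0)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(scale > 0,
                         (self.class_means - self.overall_means[None]) / scale, 0.0)
        self.d = d.T  # (p, K), signed

    def fit(self, delta: float = 0.0) -> "NumericShrunkenResults":
        if delta < 0:
            raise ValueError("delta must be >= 0")
        d_shrunk = np.sign(self.d) * np.maximum(np.abs(self.d) - delta, 0.0)
        scale = (self.m_k[None, :] * (self.s + self.s0)[:, None])  # (p, K)
        shrunk_means = (self.overall_means[:, None] + scale * d_shrunk).T  # (K, p)
        return NumericShrunkenResults(self, float(delta), d_shrunk, shrunk_means)


@dataclasses.dataclass
class NumericShrunkenResults:
    model: NumericShrunkenCentroid
    delta: float
    d_shrunk: np.ndarray      # (p, K), signed
    shrunk_means: np.ndarray  # (K, p)

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(np.abs(self.d_shrunk).max(axis=1) > 0)

    def selected_snps(self) -> list[tuple[str, np.ndarray]]:
        idx = self.selected
        order = sorted(idx, key=lambda i: (-np.abs(self.d_shrunk[i]).max(), i))
        ids = self.model.genotypes.snp_ids
        return [(ids[i], self.d_shrunk[i].copy()) for i in order]

    def predict_scores(self, data) -> np.ndarray:
        m = self.model
        calls = data.calls if isinstance(data, GenotypeMatrix) else np.asarray(data)
        if calls.ndim == 1:
            calls = calls[None, :]
        x = NumericShrunkenCentroid._RECODE[calls.astype(int)]
        w = 1.0 / (m.s + m.s0) ** 2
        scores = np.empty((x.shape[0], m.K))
        for k in range(m.K):
            scores[:, k] = (((x - self.shrunk_means[k][None, :]) ** 2)
                            * w[None, :]).sum(axis=1)
        return scores - 2.0 * np.log(m.priors)[None, :]

    def predict(self, data) -> np.ndarray:
        scores = self.predict_scores(data)
        m = self.model
        out = []
        for row in scores:
            cand = np.flatnonzero(row == row.min())
            k = min(cand, key=lambda c: (-m.priors[c], c))
            out.append(m.class_labels[k])
        return np.array(out, dtype=object)
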