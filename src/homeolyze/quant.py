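"""Expression quantification and presence calling.

Counts become RPKM (reads per kilobase of exon model per million assigned
reads); a two-component Gaussian mixture on per-accession mean log2(RPKM+1)
assigns each gene a posterior probability of being actively expressed, the
stand-in for a UPC-style expression likelihood.  Genes are "active" above
posterior 0.5; bias analyses use the stricter 0.99 operating point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import expand_units, unit_count_matrix

ACTIVE_THRESHOLD = 0.5
HIGH_CONFIDENCE = 0.99

_EM_TOL = 1e-8
_EM_MAX_ITER = 500
_VAR_FLOOR = 1e-6


def rpkm(count, gene_length_bp, library_size):
    """RPKM = 1e9 * count / (gene length * library size)."""
    gene_length_bp = np.asarray(gene_length_bp, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(gene_length_bp < 1):
        raise ValueError("gene length must be >= 1 bp")
    if np.any(library_size < 1):
        raise ValueError("library size must be >= 1 read")
    return 1e9 * np.asarray(count, dtype=float) / (gene_length_bp * library_size)


def rpkm_matrix(unit_counts: pd.DataFrame, gene_lengths: pd.Series,
                library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Genes x units RPKM matrix.

    The library size of a unit is its column sum: for a polyploid partition
    unit that is the categorized reads of that partition, for 'total' and
    diploid units all assigned (non-chimeric) reads.
    """
    lengths = gene_lengths.reindex(unit_counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise ValueError(f"no gene length for {missing}")
    if library_sizes is None:
        library_sizes = unit_counts.sum(axis=0)
    out = rpkm(
        unit_counts.to_numpy(dtype=float),
        lengths.to_numpy()[:, None],
        library_sizes.reindex(unit_counts.columns).to_numpy()[None, :],
    )
    return pd.DataFrame(out, index=unit_counts.index, columns=unit_counts.columns)


def log2_rpkm(rpkm_values):
    """log2(RPKM + 1); bounded below at 0."""
    return np.log2(np.asarray(rpkm_values, dtype=float) + 1.0)


# ---------------------------------------------------------------------------
# presence mixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureFit:
    """Fitted two-component Gaussian mixture (component 0 = background)."""

    means: tuple
    sds: tuple
    weights: tuple
    loglik: float
    n_iter: int
    converged: bool

    def posterior(self, x) -> np.ndarray:
        """P(expressed component | x)."""
        x = np.asarray(x, dtype=float)
        log_d = self._log_densities(x)
        m = np.maximum(log_d[0], log_d[1])
        num = self.weights[1] * np.exp(log_d[1] - m)
        den = num + self.weights[0] * np.exp(log_d[0] - m)
        return num / den

    def _log_densities(self, x):
        out = []
        for mu, sd in zip(self.means, self.sds):
            out.append(-0.5 * ((x - mu) / sd) ** 2 - np.log(sd)
                       - 0.5 * np.log(2 * np.pi))
        return out


def _em_once(x, mu0, mu1, sd, w1):
    n = x.size
    mu = np.array([mu0, mu1])
    var = np.array([sd ** 2, sd ** 2])
    w = np.array([1 - w1, w1])
    prev = -np.inf
    for it in range(1, _EM_MAX_ITER + 1):
        log_d = (-0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
                 - 0.5 * np.log(2 * np.pi * var[None, :]) + np.log(w[None, :]))
        m = log_d.max(axis=1)
        lse = m + np.log(np.exp(log_d - m[:, None]).sum(axis=1))
        loglik = float(lse.sum())
        resp = np.exp(log_d - lse[:, None])
        nk = resp.sum(axis=0)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, _VAR_FLOOR)
        if np.isfinite(prev) and abs(loglik - prev) <= _EM_TOL * (abs(prev) + 1.0):
            return mu, np.sqrt(var), w, loglik, it, True
        prev = loglik
    return mu, np.sqrt(var), w, loglik, _EM_MAX_ITER, False


def fit_presence_mixture(log_expr_vector) -> MixtureFit:
    """EM fit of a two-component Gaussian mixture to log2(RPKM+1) values.

    Five restarts initialize the component means from quantile pairs spread
    across the data; the best-likelihood solution is kept and components are
    ordered so the lower mean is background.  Fully deterministic.
    """
    x = np.asarray(log_expr_vector, dtype=float)
    if x.size < 50:
        raise ValueError("presence mixture needs at least 50 genes")
    if np.ptp(x) == 0:
        raise ValueError("no expression signal: all values identical")
    sd0 = float(np.std(x))
    best = None
    for q in (0.2, 0.35, 0.5, 0.65, 0.8):
        mu0 = float(np.quantile(x, q / 2))
        mu1 = float(np.quantile(x, q / 2 + 0.5))
        if mu0 == mu1:
            mu1 = mu0 + sd0
        mu, sds, w, ll, it, conv = _em_once(x, mu0, mu1, sd0 / 2, 0.5)
        if best is None or ll > best[3]:
            best = (mu, sds, w, ll, it, conv)
    mu, sds, w, ll, it, conv = best
    order = np.argsort(mu)
    return MixtureFit(
        means=tuple(float(mu[i]) for i in order),
        sds=tuple(float(sds[i]) for i in order),
        weights=tuple(float(w[i]) for i in order),
        loglik=ll,
        n_iter=it,
        converged=conv,
    )


def presence_calls(counts: pd.DataFrame, samples: pd.DataFrame,
                   gene_lengths: pd.Series) -> pd.DataFrame:
    """Per (gene, accession) expression posteriors from total-expression units.

    For each accession, replicate log2(RPKM+1) values of its 'total' (or
    diploid) units are averaged and a presence mixture fitted.  Returns a
    long table: gene_id, accession, posterior, active, high_confidence.
    """
    units = expand_units(samples)
    mat = unit_count_matrix(counts, samples)
    expr = pd.DataFrame(
        log2_rpkm(rpkm_matrix(mat, gene_lengths)),
        index=mat.index, columns=mat.columns,
    )
    frames = []
    for accession, sub in units.groupby("accession", sort=True):
        total_units = sub[sub["partition"].isin(["total", "A", "D"])]
        # diploids: single own-genome partition; polyploids: the total units
        if (sub["partition"] == "total").any():
            total_units = sub[sub["partition"] == "total"]
        mean_log = expr[total_units["unit_id"]].mean(axis=1)
        fit = fit_presence_mixture(mean_log.to_numpy())
        post = fit.posterior(mean_log.to_numpy())
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": mean_log.index,
                    "accession": accession,
                    "posterior": post,
                    "active": post > ACTIVE_THRESHOLD,
                    "high_confidence": post >= HIGH_CONFIDENCE,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# expressed sets
# ---------------------------------------------------------------------------

def expressed_sets(presence: pd.DataFrame, accessions=None) -> dict:
    """Active gene sets per accession plus their intersection.

    Returns ``{"per_accession": {acc: set}, "common": set}``; "commonly
    expressed" genes are active in every accession considered.
    """
    if accessions is None:
        accessions = sorted(presence["accession"].unique())
    per = {}
    for acc in accessions:
        sub = presence[(presence["accession"] == acc) & presence["active"]]
        per[acc] = set(sub["gene_id"])
    common = set.intersection(*per.values()) if per else set()
    return {"per_accession": per, "common": common}


def percent_expressed(n_expressed: int, n_annotated: int) -> float:
    """Percent of annotated genes expressed, to one decimal (as reported)."""
    if n_annotated <= 0:
        raise ValueError("n_annotated must be positive")
    return round(100.0 * n_expressed / n_annotated, 1)
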