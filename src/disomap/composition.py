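"""Amino-acid composition enrichment/depletion profiling.

For each of the 20 standard residues the fractional difference
``(C_query - C_background) / C_background`` is computed against a chosen
background composition, and significance is assessed by comparing
bootstrap sampling distributions of the two frequencies.  Residues are
reported in TOP-IDP order, from the most order-promoting (C) to the most
disorder-promoting (P).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import STANDARD_AMINO_ACIDS, ProteinSequence

logger = logging.getLogger(__name__)

#: TOP-IDP ranking: most order-promoting first, most disorder-promoting last.
TOP_IDP_ORDER = list("CWIYFLHVNMRTDGAKQSEP")
ORDER_PROMOTING = TOP_IDP_ORDER[:10]
DISORDER_PROMOTING = TOP_IDP_ORDER[10:]

_AA = list(STANDARD_AMINO_ACIDS)


@dataclass
class CompositionResult:
    """Per-amino-acid enrichment table (rows indexed by one-letter code)."""

    table: pd.DataFrame  # columns: c_query, c_background, frac_diff, p, significant

    def __post_init__(self) -> None:
        if set(self.table.index) != set(_AA):
            raise ValueError("composition result must cover all 20 codes")


def composition_frequencies(seq: ProteinSequence) -> pd.Series:
    """Relative frequency of each of the 20 codes (zeros included)."""
    seq.require_standard()
    counts = pd.Series(0.0, index=_AA)
    observed = pd.Series(list(seq.residues)).value_counts()
    counts.loc[observed.index] = observed.to_numpy(dtype=float)
    return counts / seq.length


def fractional_difference(c_query: float, c_background: float) -> float:
    """(C_query - C_background) / C_background; nan when the background is 0."""
    if c_query < 0 or c_background < 0:
        raise ValueError("frequencies must be non-negative")
    if c_background == 0:
        logger.warning("background frequency 0: fractional difference undefined")
        return float("nan")
    return (c_query - c_background) / c_background


def load_background(path: str | Path | None = None) -> pd.Series:
    """Load a background composition from CSV (columns ``code``, ``freq``).

    Without a path, a bundled synthetic globular-protein-like background is
    used (see ``data/background_globular_synthetic.csv``).
    """
    if path is None:
        ref = resources.files("disomap.data") / "background_globular_synthetic.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    freqs = pd.Series(df["freq"].to_numpy(float), index=df["code"].tolist())
    freqs = freqs.reindex(_AA).fillna(0.0)
    total = freqs.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"background frequencies sum to {total}, not 1")
    return freqs / total


def _welch_t(freq_a: np.ndarray, n_a: int,
             freq_b: np.ndarray, n_b: int) -> np.ndarray:
    """Two-sample (Welch) t statistic for per-code frequencies, treating
    residues as Bernoulli observations.  Zero-variance ties give t = 0."""
    var = freq_a * (1 - freq_a) / n_a + freq_b * (1 - freq_b) / n_b
    diff = freq_a - freq_b
    t = np.zeros_like(diff)
    np.divide(diff, np.sqrt(var), out=t, where=var > 0)
    t[(var == 0) & (diff != 0)] = np.inf
    return t


def composition_significance(seq: ProteinSequence,
                             background_freqs: pd.Series,
                             background_n: int = 10000,
                             iterations: int = 10000,
                             alpha: float = 0.05,
                             seed: int | None = None,
                             method: str = "ttest") -> CompositionResult:
    """Enrichment/depletion of each residue type with resampling significance.

    The observed statistic per code is a two-sample t comparing the query
    frequency (over the protein's residues) with the frequency in a
    background pseudo-sample (a multinomial draw of size ``background_n``
    from the background composition).  Its two-sided p-value is calibrated
    by Monte Carlo: per iteration, both samples are redrawn from the
    background (the null of identical composition) and the t statistic is
    recomputed; p is the fraction of null statistics at least as extreme.
    A plain Wald p from the bootstrap standard errors is badly
    anti-conservative for rare residues (tiny expected counts), which is
    why the null is simulated instead.  ``method="bootstrap_ci"`` instead
    bootstraps the query and calls significance when the
    Bonferroni-adjusted percentile CI of the frequency difference excludes
    zero.  Bonferroni m = 20, one test per code.
    """
    if iterations < 100:
        raise ValueError("iterations must be >= 100")
    if background_n < 1:
        raise ValueError("background_n must be >= 1")
    if method not in ("ttest", "bootstrap_ci"):
        raise ValueError(f"unknown method {method!r}")
    background_freqs = background_freqs.reindex(_AA).fillna(0.0)
    rng = np.random.default_rng(seed)
    c_query = composition_frequencies(seq)
    bg = background_freqs.to_numpy(float)
    n_q = seq.length

    b_obs = rng.multinomial(background_n, bg) / background_n
    t_obs = _welch_t(c_query.to_numpy(), n_q, b_obs, background_n)
    if (t_obs == 0).any() and (c_query.to_numpy() == b_obs).any():
        degenerate = [a for a, q, b in zip(_AA, c_query, b_obs) if q == b == 0]
        if degenerate:
            logger.warning("zero-variance codes %s: p reported as 1", degenerate)

    q_null = rng.multinomial(n_q, bg, size=iterations) / n_q
    b_null = rng.multinomial(background_n, bg, size=iterations) / background_n
    t_null = _welch_t(q_null, n_q, b_null, background_n)
    exceed = (np.abs(t_null) >= np.abs(t_obs)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (iterations + 1.0)

    bonferroni_alpha = alpha / 20.0
    if method == "ttest":
        significant = p < bonferroni_alpha
    else:
        q_boot = rng.multinomial(n_q, c_query.to_numpy(), size=iterations) / n_q
        diff = q_boot - b_null
        lo = np.quantile(diff, bonferroni_alpha / 2.0, axis=0)
        hi = np.quantile(diff, 1.0 - bonferroni_alpha / 2.0, axis=0)
        significant = (lo > 0) | (hi < 0)

    frac = np.array([fractional_difference(q, b)
                     for q, b in zip(c_query.to_numpy(), bg)])
    table = pd.DataFrame({
        "c_query": c_query.to_numpy(),
        "c_background": bg,
        "frac_diff": frac,
        "p": p,
        "significant": significant,
    }, index=_AA)
    return CompositionResult(table)


def order_by_topidp(result: CompositionResult) -> pd.DataFrame:
    """Reorder the result by the TOP-IDP scale and tag the two panels."""
    table = result.table.reindex(TOP_IDP_ORDER)
    if table.isna().any(axis=None):
        raise ValueError("composition result does not cover all 20 codes")
    table = table.copy()
    table["panel"] = ["order_promoting"] * 10 + ["disorder_promoting"] * 10
    return table
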