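"""Mutation-versus-selection diagnostics: ENC-plot, ENC-ratio histogram,
PR2 parity plot, neutrality regression and correspondence analysis.

Under mutation pressure alone, a gene's ENC should sit near the value
expected from its silent-site GC content,

    ENC_exp(s) = 2 + s + 29 / (s^2 + (1-s)^2),    s = GC3s,

and third-position purine/pyrimidine usage should be at parity
(A3 = T3, G3 = C3).  Systematic departures — genes far below the
expected curve, PR2 points away from (0.5, 0.5), a shallow slope of
GC12 on GC3 — indicate selection on codon choice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codon_metrics import CodonCountTable
from .genetics import GENETIC_CODE, SENSE_CODONS, SYNONYMOUS_CODONS

__all__ = [
    "expected_enc",
    "ENCRatioHistogram",
    "enc_ratio_histogram",
    "pr2_point",
    "RegressionResult",
    "neutrality_fit",
    "CoAResult",
    "correspondence_analysis",
    "gc_class_labels",
]

#: Four-fold degenerate codon boxes (third position fully free).
_FOURFOLD = tuple(
    c for c in SENSE_CODONS
    if all((c[:2] + b) in SENSE_CODONS for b in "UCAG")
    and len({GENETIC_CODE[c[:2] + b] for b in "UCAG"}) == 1
)


def expected_enc(gc3s: float | np.ndarray) -> float | np.ndarray:
    """ENC expected under mutation pressure alone at silent GC content s."""
    s = np.asarray(gc3s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("gc3s must lie in [0, 1]")
    val = 2 + s + 29.0 / (s**2 + (1 - s) ** 2)
    return float(val) if np.isscalar(gc3s) or val.ndim == 0 else val


# ENC-ratio histogram bins: eight classes of width 0.1.
_BIN_EDGES = np.round(np.arange(-0.25, 0.56, 0.1), 10)
_CLASS_VALUES = np.round(np.arange(-0.2, 0.51, 0.1), 10)


@dataclass
class ENCRatioHistogram:
    """Distribution of (ENC_exp - ENC_obs) / ENC_exp over genes."""

    counts: np.ndarray          # per class, len 8
    n_below: int                # ratio < -0.25
    n_above: int                # ratio >= 0.55
    class_values: np.ndarray = field(default_factory=lambda: _CLASS_VALUES.copy())
    bin_edges: np.ndarray = field(default_factory=lambda: _BIN_EDGES.copy())

    @property
    def n_in_range(self) -> int:
        return int(self.counts.sum())

    @property
    def rates(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total else self.counts.astype(float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "class_limit": [
                    f"{lo:g}~{hi:g}"
                    for lo, hi in zip(self.bin_edges[:-1], self.bin_edges[1:])
                ],
                "class_value": self.class_values,
                "count": self.counts,
                "rate": self.rates,
            }
        )
        if self.n_below or self.n_above:
            df.loc[len(df)] = ["out_of_range", math.nan,
                               self.n_below + self.n_above, math.nan]
        return df


def enc_ratio_histogram(
    enc_obs: np.ndarray | pd.Series, gc3s: np.ndarray | pd.Series
) -> ENCRatioHistogram:
    """Bin per-gene ENC ratios (ENC_exp - ENC_obs)/ENC_exp into the eight
    0.1-wide classes centred on -0.2 ... 0.5; out-of-range genes are
    tallied separately, genes with undefined ENC dropped."""
    enc_obs = np.asarray(enc_obs, dtype=float)
    gc3s = np.asarray(gc3s, dtype=float)
    ok = ~(np.isnan(enc_obs) | np.isnan(gc3s))
    ratio = (expected_enc(gc3s[ok]) - enc_obs[ok]) / expected_enc(gc3s[ok])
    counts, _ = np.histogram(ratio, bins=_BIN_EDGES)
    return ENCRatioHistogram(
        counts=counts,
        n_below=int((ratio < _BIN_EDGES[0]).sum()),
        n_above=int((ratio >= _BIN_EDGES[-1]).sum()),
    )


def pr2_point(
    counts: CodonCountTable, fourfold_only: bool = False
) -> tuple[float, float]:
    """PR2-plot coordinates (G3/(G3+C3), A3/(A3+T3)) for one gene.

    Third positions of sense codons excluding AUG and UGG by default;
    ``fourfold_only`` restricts to four-fold degenerate codon boxes.
    A zero denominator yields ``nan`` for that coordinate.
    """
    codons = _FOURFOLD if fourfold_only else SYNONYMOUS_CODONS
    base_count = {b: 0 for b in "ACGU"}
    for c in codons:
        base_count[c[2]] += counts[c]
    g, c_ = base_count["G"], base_count["C"]
    a, u = base_count["A"], base_count["U"]
    x = g / (g + c_) if (g + c_) > 0 else math.nan
    y = a / (a + u) if (a + u) > 0 else math.nan
    return x, y


@dataclass(frozen=True)
class RegressionResult:
    """Neutrality regression of GC12 on GC3 with slope-share heuristic."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int

    @property
    def mutation_share(self) -> float:
        """Percent of usage variation attributed to mutation: |slope|*100.

        The absolute value is taken so a (rare) negative slope still maps
        to a share in [0, 100]; callers should flag negative slopes.
        """
        return min(abs(self.slope), 1.0) * 100

    @property
    def selection_share(self) -> float:
        return 100 - self.mutation_share


def neutrality_fit(
    gc3: np.ndarray | pd.Series, gc12: np.ndarray | pd.Series
) -> RegressionResult:
    """Unweighted least-squares fit of GC12 on GC3 across genes.

    A slope near 1 with a strong correlation indicates mutation-driven
    codon usage; a slope near 0, selection-driven.
    """
    gc3 = np.asarray(gc3, dtype=float)
    gc12 = np.asarray(gc12, dtype=float)
    ok = ~(np.isnan(gc3) | np.isnan(gc12))
    gc3, gc12 = gc3[ok], gc12[ok]
    if len(gc3) < 3:
        raise ValueError("need at least 3 genes")
    if np.ptp(gc3) == 0:
        raise ValueError("GC3 has zero variance")
    fit = stats.linregress(gc3, gc12)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=len(gc3),
    )


@dataclass
class CoAResult:
    """Correspondence analysis of a genes x codons matrix."""

    row_coords: pd.DataFrame      # genes on the principal axes
    col_coords: pd.DataFrame      # codons on the principal axes
    inertia: np.ndarray           # squared singular values per axis
    total_inertia: float

    @property
    def inertia_percent(self) -> np.ndarray:
        if self.total_inertia == 0:
            return np.zeros_like(self.inertia)
        return 100 * self.inertia / self.total_inertia


def correspondence_analysis(
    matrix: pd.DataFrame, n_axes: int | None = None
) -> CoAResult:
    """Correspondence analysis via SVD of standardised residuals.

    The input is a non-negative genes x codons matrix (per-gene RSCU
    values by convention; raw counts also work).  With correspondence
    matrix P = X / total and margins r, c, the residuals
    D_r^{-1/2} (P - r c^T) D_c^{-1/2} are decomposed by SVD; principal
    coordinates scale the singular vectors by the singular values, and
    each axis explains inertia sigma_k^2 / sum sigma^2.  All-zero rows
    or columns are dropped with a warning.
    """
    X = matrix.fillna(0.0).to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("matrix must be non-negative")
    row_ok = X.sum(axis=1) > 0
    col_ok = X.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn(
            f"dropping {int((~row_ok).sum())} all-zero rows and "
            f"{int((~col_ok).sum())} all-zero columns"
        )
    X = X[row_ok][:, col_ok]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 non-zero rows")
    index = matrix.index[row_ok]
    columns = matrix.columns[col_ok]

    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)

    keep = sig > 1e-12 * max(sig[0], 1.0)
    U, sig, Vt = U[:, keep], sig[keep], Vt[keep]
    if n_axes is not None:
        U, sig, Vt = U[:, :n_axes], sig[:n_axes], Vt[:n_axes]

    axes = [f"axis{i + 1}" for i in range(len(sig))]
    row_coords = pd.DataFrame(
        (U * sig) / np.sqrt(r)[:, None], index=index, columns=axes
    )
    col_coords = pd.DataFrame(
        (Vt.T * sig) / np.sqrt(c)[:, None], index=columns, columns=axes
    )
    inertia = sig**2
    return CoAResult(
        row_coords=row_coords,
        col_coords=col_coords,
        inertia=inertia,
        total_inertia=float((S**2).sum()),
    )


def gc_class_labels(gc: np.ndarray | pd.Series) -> list[str]:
    """GC-content classes: low < 45%, mid in [45%, 60%), high >= 60%."""
    labels = []
    for g in np.asarray(gc, dtype=float):
        if g < 0.45:
            labels.append("low")
        elif g < 0.60:
            labels.append("mid")
        else:
            labels.append("high")
    return labels
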