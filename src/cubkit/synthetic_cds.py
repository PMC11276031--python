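"""Synthetic CDS sets with known statistical structure.

Genes are generated codon by codon: an AUG start, interior codons drawn
independently (an amino acid from a composition vector, then a codon
from that amino acid's preference vector), and a sampled stop codon.
Because every sampling distribution is known exactly, the generator
emits a *truth record* alongside the sequences: the per-gene codon
distribution, expected GC fractions by position, stratum labels and the
planted codon preferences.  Tests recover these quantities from the
sequences and compare against the truth.

Controls:

* a scalar ``bias`` in [0, 1] interpolating uniform synonymous usage
  (ENC 61) towards one codon per family (ENC 20);
* explicit per-amino-acid preference vectors;
* a ``target_gc3`` that tilts third-position base odds within each
  family, calibrated by root finding so the expected GC3 hits the
  target;
* a two-strata design (``strata``) planting a highly biased
  subpopulation whose preferred codons a delta-RSCU screen should
  recover;
* a mutational ``gradient`` sweeping per-gene GC3 targets and
  amino-acid composition between two endpoints, giving a known
  neutrality-plot slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .genetics import AA_TO_CODONS, START_CODON, STOP_CODONS
from .sequence_io import GeneRecord

__all__ = [
    "GenomeSpec",
    "StrataSpec",
    "GradientSpec",
    "generate_genome",
    "fixture_invalid_cds",
    "uniform_preferences",
    "biased_preferences",
    "planted_screen_spec",
    "mutation_gradient_spec",
]

AMINO_ACIDS = tuple(sorted(AA_TO_CODONS))  # 20 amino acids
_DEGENERATE = tuple(a for a in AMINO_ACIDS if len(AA_TO_CODONS[a]) > 1)


def uniform_preferences() -> dict[str, dict[str, float]]:
    """Uniform codon preference vectors for every amino acid."""
    return {
        aa: {c: 1.0 / len(codons) for c in codons}
        for aa, codons in AA_TO_CODONS.items()
    }


def biased_preferences(bias: float) -> dict[str, dict[str, float]]:
    """Interpolate uniform usage towards one codon per family.

    ``bias`` 0 is uniform; 1 concentrates each family on its
    alphabetically first codon (a fixed, arbitrary choice).
    """
    if not 0 <= bias <= 1:
        raise ValueError("bias must be in [0, 1]")
    prefs = {}
    for aa, codons in AA_TO_CODONS.items():
        first = min(codons)
        n = len(codons)
        prefs[aa] = {
            c: (1 - bias) / n + (bias if c == first else 0.0) for c in codons
        }
    return prefs


@dataclass(frozen=True)
class StrataSpec:
    """A planted high-expression stratum with its own codon preferences."""

    fraction: float = 0.10
    preferences: Mapping[str, Mapping[str, float]] | None = None
    bias: float | None = None


@dataclass(frozen=True)
class GradientSpec:
    """Per-gene mutational gradient: GC3 targets swept over a range while
    the amino-acid composition interpolates between two endpoint vectors,
    so expected GC12 co-varies with expected GC3 at a known slope."""

    gc3_range: tuple[float, float] = (0.3, 0.7)
    aa_weights_low: Mapping[str, float] | None = None
    aa_weights_high: Mapping[str, float] | None = None


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic multi-gene CDS set.

    Lengths are in codons including start and stop; the minimum of 100
    codons (300 nt) keeps every generated gene past the CDS screen.
    """

    n_genes: int = 200
    min_codons: int = 100
    max_codons: int = 500
    aa_weights: Mapping[str, float] | None = None
    preferences: Mapping[str, Mapping[str, float]] | None = None
    bias: float | None = None
    target_gc3: float | None = None
    strata: StrataSpec | None = None
    gradient: GradientSpec | None = None
    stop_weights: Mapping[str, float] = field(
        default_factory=lambda: {"UAA": 1 / 3, "UAG": 1 / 3, "UGA": 1 / 3}
    )

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.min_codons < 100:
            raise ValueError("genes must be at least 100 codons (300 nt)")
        if self.max_codons < self.min_codons:
            raise ValueError("max_codons < min_codons")
        if self.preferences is not None and self.bias is not None:
            raise ValueError("give preferences or bias, not both")


def _normalize_weights(w: Mapping[str, float], keys: Sequence[str]) -> np.ndarray:
    arr = np.array([float(w.get(k, 0.0)) for k in keys])
    if (arr < 0).any() or arr.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    return arr / arr.sum()


def _resolve_prefs(
    preferences: Mapping[str, Mapping[str, float]] | None, bias: float | None
) -> dict[str, np.ndarray]:
    if preferences is None:
        preferences = uniform_preferences() if bias is None else biased_preferences(bias)
    out = {}
    for aa, codons in AA_TO_CODONS.items():
        vec = preferences.get(aa)
        if vec is None:
            out[aa] = np.full(len(codons), 1.0 / len(codons))
        else:
            out[aa] = _normalize_weights(vec, codons)
    return out


def _tilted_prefs(
    prefs: dict[str, np.ndarray], t: float
) -> dict[str, np.ndarray]:
    """Reweight codons by t (G/C-ending) vs 1-t (A/U-ending) per family."""
    out = {}
    for aa, codons in AA_TO_CODONS.items():
        w = prefs[aa] * np.array(
            [t if c[2] in "GC" else 1 - t for c in codons]
        )
        if w.sum() <= 0:
            raise ValueError(f"tilt {t} leaves no usable codon for {aa}")
        out[aa] = w / w.sum()
    return out


def _expected_gc3(
    aa_probs: np.ndarray, prefs: dict[str, np.ndarray], t: float | None
) -> float:
    p = prefs if t is None else _tilted_prefs(prefs, t)
    total = 0.0
    for aa, f in zip(AMINO_ACIDS, aa_probs):
        codons = AA_TO_CODONS[aa]
        gc = sum(w for c, w in zip(codons, p[aa]) if c[2] in "GC")
        total += f * gc
    return total


def _solve_tilt(
    aa_probs: np.ndarray, prefs: dict[str, np.ndarray], target: float
) -> float:
    """Third-position tilt t such that expected GC3 equals the target."""
    eps = 1e-9
    lo, hi = _expected_gc3(aa_probs, prefs, eps), _expected_gc3(aa_probs, prefs, 1 - eps)
    if not (lo - 1e-6 <= target <= hi + 1e-6):
        raise ValueError(
            f"target GC3 {target} infeasible; achievable range "
            f"[{lo:.4f}, {hi:.4f}] under these preferences"
        )
    if target <= lo:
        return eps
    if target >= hi:
        return 1 - eps
    return brentq(
        lambda t: _expected_gc3(aa_probs, prefs, t) - target, eps, 1 - eps,
        xtol=1e-12,
    )


def _codon_distribution(
    aa_probs: np.ndarray, prefs: dict[str, np.ndarray]
) -> dict[str, float]:
    """Exact interior-codon sampling distribution."""
    dist: dict[str, float] = {}
    for aa, f in zip(AMINO_ACIDS, aa_probs):
        for c, w in zip(AA_TO_CODONS[aa], prefs[aa]):
            dist[c] = f * w
    return dist


def _expected_gc_by_position(dist: Mapping[str, float]) -> dict[str, float]:
    gc = [0.0, 0.0, 0.0]
    for c, p in dist.items():
        for k in range(3):
            if c[k] in "GC":
                gc[k] += p
    return {
        "gc1": gc[0], "gc2": gc[1], "gc3": gc[2],
        "gc12": (gc[0] + gc[1]) / 2,
    }


def generate_genome(
    spec: GenomeSpec, seed: int
) -> tuple[list[GeneRecord], dict]:
    """Generate a CDS set and its truth record, reproducibly from a seed.

    Every gene starts with AUG, ends with a sampled stop and contains no
    internal stop, so the whole output passes the CDS screen.  The truth
    record holds per-gene stratum labels, the exact interior codon
    distributions and their expected GC fractions by position.
    """
    rng = np.random.default_rng(seed)
    aa_default = (
        _normalize_weights(spec.aa_weights, AMINO_ACIDS)
        if spec.aa_weights is not None
        else np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    )
    base_prefs = _resolve_prefs(spec.preferences, spec.bias)

    # stratum assignment: a deterministic permutation of gene indices
    labels = np.array(["bulk"] * spec.n_genes, dtype=object)
    if spec.strata is not None:
        n_high = max(1, round(spec.strata.fraction * spec.n_genes))
        high_idx = rng.permutation(spec.n_genes)[:n_high]
        labels[high_idx] = "high"
        high_prefs = _resolve_prefs(spec.strata.preferences, spec.strata.bias)
    else:
        high_prefs = base_prefs

    stops = list(spec.stop_weights)
    stop_p = _normalize_weights(spec.stop_weights, stops)

    # per-gene sampling distributions
    per_gene: list[dict] = []
    cache: dict[tuple, dict[str, np.ndarray]] = {}
    for i in range(spec.n_genes):
        if spec.gradient is not None:
            m = 0.5 if spec.n_genes == 1 else i / (spec.n_genes - 1)
            g = spec.gradient
            w_lo = (
                _normalize_weights(g.aa_weights_low, AMINO_ACIDS)
                if g.aa_weights_low is not None else aa_default
            )
            w_hi = (
                _normalize_weights(g.aa_weights_high, AMINO_ACIDS)
                if g.aa_weights_high is not None else aa_default
            )
            aa_probs = (1 - m) * w_lo + m * w_hi
            target = g.gc3_range[0] + m * (g.gc3_range[1] - g.gc3_range[0])
        else:
            aa_probs = aa_default
            target = spec.target_gc3
        prefs = high_prefs if labels[i] == "high" else base_prefs
        if target is not None:
            t = _solve_tilt(aa_probs, prefs, target)
            prefs = _tilted_prefs(prefs, t)
        dist = _codon_distribution(aa_probs, prefs)
        per_gene.append({"aa_probs": aa_probs, "prefs": prefs, "dist": dist})

    genes: list[GeneRecord] = []
    truth_genes = []
    codon_arrays = {
        aa: np.array(AA_TO_CODONS[aa]) for aa in AMINO_ACIDS
    }
    for i, info in enumerate(per_gene):
        n_codons = int(rng.integers(spec.min_codons, spec.max_codons + 1))
        n_interior = n_codons - 2
        aa_idx = rng.choice(len(AMINO_ACIDS), size=n_interior, p=info["aa_probs"])
        interior = np.empty(n_interior, dtype=object)
        for j, aa in enumerate(AMINO_ACIDS):
            mask = aa_idx == j
            k = int(mask.sum())
            if k:
                interior[mask] = rng.choice(
                    codon_arrays[aa], size=k, p=info["prefs"][aa]
                )
        stop = stops[int(rng.choice(len(stops), p=stop_p))]
        seq = START_CODON + "".join(interior) + stop
        gid = f"gene{i + 1:05d}"
        genes.append(GeneRecord(gid, seq))
        truth_genes.append(
            {
                "id": gid,
                "stratum": str(labels[i]),
                "n_codons": n_codons,
                "codon_distribution": info["dist"],
                "expected": _expected_gc_by_position(info["dist"]),
            }
        )

    truth = {
        "seed": seed,
        "n_genes": spec.n_genes,
        "strata_fraction": spec.strata.fraction if spec.strata else None,
        "genes": truth_genes,
    }
    return genes, truth


def planted_screen_spec(
    planted: Sequence[str] | None = None,
    n_genes: int = 200,
    min_codons: int = 300,
    max_codons: int = 500,
    fraction: float = 0.10,
    bulk_weight: float = 1.6,
    high_weight: float = 8.0,
) -> GenomeSpec:
    """Two-strata genome whose delta-RSCU screen truth is ``planted``.

    Emulates translational selection: one designated optimal codon per
    synonymous subfamily (default: the alphabetically last codon of each
    split-scheme subfamily) is mildly enriched genome-wide
    (``bulk_weight``) and strongly enriched in the planted
    high-expression stratum (``high_weight``).  Every codon's RSCU then
    sits at a clear margin from both 1 and the screen threshold, and the
    stratum's ENC lies far below the bulk, so the high-expression group
    and the planted codon set are recovered cleanly.  A custom
    ``planted`` set should still cover one codon per subfamily: families
    it leaves out sit at the no-bias boundary where the screen's flags
    are coin flips of sampling noise.
    """
    from .genetics import SPLIT

    if planted is None:
        planted = [max(fam) for fam in SPLIT.families if len(fam) > 1]
    planted_set = set(planted)
    for fam in SPLIT.families:
        if len(planted_set & set(fam)) > 1:
            raise ValueError("at most one planted codon per subfamily")

    def prefs(weight: float) -> dict[str, dict[str, float]]:
        return {
            aa: {c: (weight if c in planted_set else 1.0) for c in codons}
            for aa, codons in AA_TO_CODONS.items()
        }

    return GenomeSpec(
        n_genes=n_genes,
        min_codons=min_codons,
        max_codons=max_codons,
        preferences=prefs(bulk_weight),
        strata=StrataSpec(fraction=fraction, preferences=prefs(high_weight)),
    )


def mutation_gradient_spec(
    n_genes: int = 500,
    gc3_range: tuple[float, float] = (0.25, 0.75),
    min_codons: int = 200,
    max_codons: int = 400,
) -> GenomeSpec:
    """Pure-mutation genome: GC3 swept across genes while the amino-acid
    composition shifts between AU-rich and GC-rich endpoint vectors, so
    GC12 tracks GC3 at a slope fixed by the endpoints (recorded exactly
    in the truth record)."""
    gc_rich = set("AGPRV")
    au_rich = set("KNIFYL")
    w_low = {aa: (2.0 if aa in au_rich else 1.0) for aa in AMINO_ACIDS}
    w_high = {aa: (2.0 if aa in gc_rich else 1.0) for aa in AMINO_ACIDS}
    return GenomeSpec(
        n_genes=n_genes,
        min_codons=min_codons,
        max_codons=max_codons,
        gradient=GradientSpec(
            gc3_range=gc3_range, aa_weights_low=w_low, aa_weights_high=w_high
        ),
    )


def fixture_invalid_cds() -> str:
    """Deterministic FASTA exercising each CDS screening rule once.

    Seven records: one valid control and one violator per rule (frame,
    length, ambiguous base, wrong start, missing stop, internal stop).
    """
    sense = "GCU"  # Ala filler codon
    body = sense * 98  # 98 interior codons -> 300 nt with start and stop

    records = [
        ("valid_control", "AUG" + body + "UAA"),
        ("frameshifted", ("AUG" + body + "UAA")[:-1]),           # 299 nt
        ("too_short", "AUG" + sense * 8 + "UAA"),                # 30 nt
        ("ambiguous_base", "AUG" + "GCN" + sense * 97 + "UAA"),
        ("wrong_start", "GCG" + body + "UAA"),
        ("missing_stop", "AUG" + body + "GCC"),
        ("internal_stop", "AUG" + sense * 49 + "UGA" + sense * 48 + "UAA"),
    ]
    lines = []
    for name, seq in records:
        lines.append(f">{name}")
        lines.append(seq)
    return "\n".join(lines) + "\n"
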