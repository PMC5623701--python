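"""Column conservation estimators with background/matrix sweeps.

Six estimators score how conserved an alignment column is, each oriented so
that *higher means more conserved* and expressed in bits (log base 2):

- ``shannon_entropy`` — complement of the residue Shannon entropy,
  ``log2(20) - H(p)``;
- ``property_entropy`` — the same complement computed after pooling the 20
  amino acids into physicochemical property classes;
- ``relative_entropy`` — Kullback–Leibler divergence of the column
  distribution from a background composition;
- ``js_divergence`` — Jensen–Shannon divergence from the background, a
  bounded, symmetrized relative entropy;
- ``vn_entropy`` — complement of the von Neumann entropy of a density matrix
  that couples the column distribution with a residue-similarity matrix, so
  that columns mixing similar residues still score as conserved;
- ``sum_of_pairs`` — mean pairwise similarity of the column's residues under
  a substitution matrix.

Background compositions (BLOSUM62-derived, Swiss-Prot, Pfam) are bundled;
substitution matrices are the standard BLOSUM series (35, 40, 45, 50, 62,
80, 100).  A column is *identified* by a method when its gap-adjusted score
falls in the top fraction (default 5%) of columns; the consensus operation
intersects the identified sets over every background x matrix combination,
which suppresses columns whose high score is an artifact of one particular
parameterization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from math import floor, log2
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment import AA20, GAP, Alignment
from .conservation import ColumnProfile, column_profile

LOG2_20 = log2(20.0)

BACKGROUND_NAMES = ("blosum62", "swissprot", "pf")
MATRIX_NAMES = ("blosum62", "blosum35", "blosum40", "blosum45",
                "blosum50", "blosum80", "blosum100")
METHOD_NAMES = ("js_divergence", "property_entropy", "vn_entropy",
                "relative_entropy", "shannon_entropy", "sum_of_pairs")

#: Default disjoint property partition of the 20 amino acids: aliphatic/
#: small hydrophobic, aromatic+histidine, polar uncharged, basic, acidic,
#: and the conformationally special glycine/proline.
DEFAULT_PROPERTY_PARTITION: tuple[frozenset[str], ...] = tuple(
    frozenset(s) for s in ("AVLIMC", "FWYH", "STNQ", "KR", "DE", "GP"))

_AA_INDEX = {a: i for i, a in enumerate(AA20)}


@dataclass(frozen=True)
class BackgroundDistribution:
    """A strictly positive amino-acid frequency prior over the 20 residues."""

    name: str
    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (20,):
            raise ValueError("background must have 20 entries")
        if (q <= 0).any():
            raise ValueError(f"background {self.name!r} has non-positive mass")
        if abs(q.sum() - 1.0) > 1e-9:
            raise ValueError(f"background {self.name!r} does not sum to 1")
        object.__setattr__(self, "q", q)


def _load_json(name: str) -> dict:
    with resources.files("groupcons.data").joinpath(name).open() as fh:
        return json.load(fh)


_BACKGROUNDS: dict[str, BackgroundDistribution] | None = None


def get_background(name: str) -> BackgroundDistribution:
    """Bundled background by name; 'uniform' is always available."""
    global _BACKGROUNDS
    if name == "uniform":
        return BackgroundDistribution("uniform", np.full(20, 0.05))
    if _BACKGROUNDS is None:
        raw = _load_json("backgrounds.json")
        assert raw["alphabet"] == AA20
        _BACKGROUNDS = {
            k: BackgroundDistribution(k, np.array(v) / np.sum(v))
            for k, v in raw.items() if k != "alphabet"}
    try:
        return _BACKGROUNDS[name]
    except KeyError:
        raise KeyError(f"unknown background {name!r}; "
                       f"choose from {BACKGROUND_NAMES + ('uniform',)}") from None


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 20x20 substitution score matrix and its similarity form.

    ``similarity`` rescales the raw scores into [0, 1] with a unit diagonal:
    scores are first min-max normalized, then divided by the geometric mean
    of the diagonal entries of the two residues involved, and clipped to 1.
    """

    name: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.scores, dtype=float)
        if m.shape != (20, 20) or not np.allclose(m, m.T):
            raise ValueError(f"matrix {self.name!r} is not symmetric 20x20")
        object.__setattr__(self, "scores", m)

    @property
    def similarity(self) -> np.ndarray:
        m = self.scores
        s = (m - m.min()) / (m.max() - m.min())
        d = np.sqrt(np.outer(np.diag(s), np.diag(s)))
        s = np.minimum(s / d, 1.0)
        np.fill_diagonal(s, 1.0)
        return s


_MATRICES: dict[str, SubstitutionMatrix] = {}


def get_matrix(name: str) -> SubstitutionMatrix:
    """BLOSUM matrix by name (e.g. 'blosum62'), restricted to the 20 aa."""
    if name == "identity":
        return SubstitutionMatrix("identity", np.eye(20))
    if name not in _MATRICES:
        from biotite.sequence import ProteinSequence
        from biotite.sequence.align import SubstitutionMatrix as BtMatrix
        alph = ProteinSequence.alphabet
        bt = BtMatrix(alph, alph, name.upper())
        full = np.asarray(bt.score_matrix(), dtype=float)
        sym = list(alph)
        idx = [sym.index(a) for a in AA20]
        _MATRICES[name] = SubstitutionMatrix(name, full[np.ix_(idx, idx)])
    return _MATRICES[name]


# ---------------------------------------------------------------------------
# scalar estimators


def _check_distribution(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (20,):
        raise ValueError("expected a 20-vector over the amino acids")
    if (p < -1e-12).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("p is not a probability distribution")
    return np.clip(p, 0.0, None)


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy of a residue distribution, in bits."""
    p = _check_distribution(p)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def relative_entropy(p: np.ndarray, q: np.ndarray) -> float:
    """Kullback–Leibler divergence D(p || q) in bits; q strictly positive."""
    p = _check_distribution(p)
    q = np.asarray(q, dtype=float)
    if (q <= 0).any():
        raise ValueError("background q must be strictly positive")
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / q[nz])).sum())


def js_divergence(p: np.ndarray, q: np.ndarray, lam: float = 0.5) -> float:
    """Jensen–Shannon divergence in bits; bounded by 1 at lam = 0.5."""
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must lie strictly between 0 and 1")
    p = _check_distribution(p)
    q = _check_distribution(q)
    r = lam * p + (1 - lam) * q
    # r may have zeros only where both p and q are zero; such terms vanish
    def _kl(a: np.ndarray) -> float:
        nz = a > 0
        return float((a[nz] * np.log2(a[nz] / r[nz])).sum())
    return lam * _kl(p) + (1 - lam) * _kl(q)


def property_entropy(p: np.ndarray,
                     partition: Sequence[frozenset[str]] = DEFAULT_PROPERTY_PARTITION,
                     ) -> float:
    """Shannon entropy (bits) of p pooled into property classes."""
    covered = set().union(*partition)
    if covered != set(AA20) or sum(len(c) for c in partition) != 20:
        raise ValueError("property partition must cover the 20 amino acids disjointly")
    p = _check_distribution(p)
    pooled = np.array([sum(p[_AA_INDEX[a]] for a in cls) for cls in partition])
    nz = pooled[pooled > 0]
    return float(-(nz * np.log2(nz)).sum())


def sum_of_pairs(column_residues: str | Sequence[str],
                 matrix: SubstitutionMatrix | np.ndarray) -> float:
    """Mean pairwise matrix score over the column's non-gap residues.

    Returns NaN when fewer than two scoreable residues are present.
    """
    m = matrix.scores if isinstance(matrix, SubstitutionMatrix) else np.asarray(matrix)
    idx = [_AA_INDEX[c] for c in column_residues if c in _AA_INDEX]
    n = len(idx)
    if n < 2:
        return float("nan")
    counts = np.bincount(idx, minlength=20).astype(float)
    total = 0.5 * (counts @ m @ counts - (counts * np.diag(m)).sum())
    return float(total / (n * (n - 1) / 2))


def vn_entropy(p: np.ndarray, matrix: SubstitutionMatrix | np.ndarray) -> float:
    """Von Neumann entropy (bits) of rho = D S D / tr(D S D), D = diag(sqrt p).

    With the identity similarity matrix this reduces exactly to the Shannon
    entropy of p.
    """
    s = matrix.similarity if isinstance(matrix, SubstitutionMatrix) else np.asarray(matrix)
    p = _check_distribution(p)
    d = np.sqrt(p)
    rho = s * np.outer(d, d)
    tr = np.trace(rho)
    if tr <= 0:
        raise ValueError("zero-trace density matrix")
    rho /= tr
    lam = np.linalg.eigvalsh(rho)
    lam = lam[lam > 1e-15]
    return float(-(lam * np.log2(lam)).sum())


# ---------------------------------------------------------------------------
# alignment-level scoring


def column_distribution(profile: ColumnProfile, pseudocount: float = 1e-6) -> np.ndarray:
    """Non-gap frequency 20-vector with a small pseudocount, renormalized."""
    freqs = profile.nongap_frequencies()
    p = np.array([freqs[a] for a in AA20]) + pseudocount
    return p / p.sum()


def score_column(profile: ColumnProfile, column: str, method: str,
                 background: BackgroundDistribution,
                 matrix: SubstitutionMatrix,
                 pseudocount: float = 1e-6) -> float:
    """Raw conservation score (higher = more conserved) of one column."""
    if profile.n_nongap < 2:
        return float("nan")
    p = column_distribution(profile, pseudocount)
    if method == "shannon_entropy":
        return LOG2_20 - shannon_entropy(p)
    if method == "property_entropy":
        return log2(len(DEFAULT_PROPERTY_PARTITION)) - property_entropy(p)
    if method == "relative_entropy":
        return relative_entropy(p, background.q)
    if method == "js_divergence":
        return js_divergence(p, background.q)
    if method == "vn_entropy":
        return LOG2_20 - vn_entropy(p, matrix)
    if method == "sum_of_pairs":
        return sum_of_pairs(column, matrix.similarity)
    raise ValueError(f"unknown method {method!r}")


def score_alignment(alignment: Alignment, method: str,
                    background: str | BackgroundDistribution = "blosum62",
                    matrix: str | SubstitutionMatrix = "blosum62",
                    pseudocount: float = 1e-6,
                    gap_adjust: bool = True) -> pd.DataFrame:
    """Score every column; returns index, raw and gap-adjusted scores, rank.

    The gap adjustment multiplies the raw score by the column's non-gap
    fraction, so heavily gapped columns cannot be called conserved on the
    strength of a few residues.  Rank 1 is the most conserved column (dense
    ranking of the gap-adjusted score; NaN columns are unranked).
    """
    bg = get_background(background) if isinstance(background, str) else background
    mat = get_matrix(matrix) if isinstance(matrix, str) else matrix
    rows = []
    for i in range(1, alignment.n_columns + 1):
        prof = column_profile(alignment, i)
        col = alignment.column(i)
        raw = score_column(prof, col, method, bg, mat, pseudocount)
        frac = prof.n_nongap / prof.n_total
        adj = raw * frac if gap_adjust else raw
        rows.append((i, raw, adj))
    df = pd.DataFrame(rows, columns=["index", "score", "gap_adjusted"])
    df["rank"] = df["gap_adjusted"].rank(method="dense", ascending=False)
    df["method"] = method
    df["background"] = bg.name
    df["matrix"] = mat.name
    return df


def identified_columns(scores: pd.DataFrame, top_fraction: float = 0.05) -> set[int]:
    """Columns in the top ``top_fraction`` of gap-adjusted scores.

    The identified set is the largest set of columns not exceeding the
    fraction (at least one column); ties are resolved deterministically in
    favour of the lower alignment index.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    valid = scores.dropna(subset=["gap_adjusted"])
    k = max(1, floor(top_fraction * len(valid)))
    ordered = valid.sort_values(["gap_adjusted", "index"],
                                ascending=[False, True], kind="mergesort")
    return set(ordered["index"].head(k).astype(int))


def consensus_identified(alignment: Alignment, method: str,
                         backgrounds: Iterable[str] = BACKGROUND_NAMES,
                         matrices: Iterable[str] = MATRIX_NAMES,
                         top_fraction: float = 0.05,
                         pseudocount: float = 1e-6,
                         gap_adjust: bool = True) -> set[int]:
    """Intersection of identified sets over every background x matrix run.

    Methods that ignore one of the two parameters are still run per
    combination, so the intersection semantics are uniform across methods.
    """
    consensus: set[int] | None = None
    for bg in backgrounds:
        for mat in matrices:
            scores = score_alignment(alignment, method, bg, mat,
                                     pseudocount, gap_adjust)
            ident = identified_columns(scores, top_fraction)
            consensus = ident if consensus is None else (consensus & ident)
    if consensus is None:
        raise ValueError("no background/matrix combinations configured")
    return consensus


def score_sweep(alignment: Alignment, methods: Iterable[str] = METHOD_NAMES,
                backgrounds: Iterable[str] = BACKGROUND_NAMES,
                matrices: Iterable[str] = MATRIX_NAMES,
                top_fraction: float = 0.05) -> pd.DataFrame:
    """Long-format score table over methods x backgrounds x matrices."""
    frames = []
    for method in methods:
        for bg in backgrounds:
            for mat in matrices:
                df = score_alignment(alignment, method, bg, mat)
                ident = identified_columns(df, top_fraction)
                df["identified"] = df["index"].isin(ident)
                frames.append(df)
    return pd.concat(frames, ignore_index=True)
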