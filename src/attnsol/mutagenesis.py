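"""In-silico mutagenesis: single and tandem-pair scans, synergy, structure.

The effect of a substitution is scored as the change in predicted
solubility, dS = MUT_score - WT_score (positive = solubilizing).  For
pairs of substitutions at distinct positions i < j, the additive
expectation dS_single = dS_i + dS_j is compared against the joint
effect dS_pair of implementing both at once; their difference
dE = dS_single - dS_pair measures epistasis (negative dE: the pair acts
more strongly than the sum of its parts).

A full tandem scan enumerates 20 substitutions per position (the
wildtype identity included, so self-substitutions score exactly zero)
at every unordered pair of distinct positions:
(L*20*(L-1)*20)/2 pairs, e.g. 2,101,200 for a 103-residue protein.
Scans stream in fixed-size batches so memory stays bounded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from scipy import stats

from .model import ModelParams, _forward_batch
from .sequence_io import AMINO_ACIDS, DEFAULT_VOCABULARY, EncodedBatch, Vocabulary, sanitize

logger = logging.getLogger(__name__)

__all__ = [
    "MutationEffect",
    "PairEffect",
    "SynergyMap",
    "SeparationProfile",
    "single_scan",
    "pair_scan",
    "pair_count",
    "synergy_map",
    "separation_profile",
    "residue_distance_profile",
    "correlate_synergy_distance",
]


@dataclass(frozen=True)
class MutationEffect:
    position: int  # 1-based
    wt_aa: str
    mut_aa: str
    delta_s: float


@dataclass(frozen=True)
class PairEffect:
    """A tandem pair of substitutions at positions i < j (1-based)."""

    i: int
    j: int
    aa_i: str
    aa_j: str
    delta_s_pair: float
    delta_s_single: float

    @property
    def delta_e(self) -> float:
        return self.delta_s_single - self.delta_s_pair


@dataclass
class SynergyMap:
    """L x L matrix of mean dE per position pair; diagonal is NaN."""

    matrix: np.ndarray

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SeparationProfile:
    """Mean and median of a pairwise quantity per sequence separation."""

    separations: np.ndarray  # int, ascending
    mean: np.ndarray
    median: np.ndarray


def _cast_params(params: ModelParams, dtype: np.dtype) -> ModelParams:
    """A view of the model with weights cast to ``dtype`` (no-op if equal).

    Scans compare sigmoid outputs whose differences are read at the
    1e-5 level; single precision carries ~1e-7 absolute noise there, so
    it is the scan default (roughly twice as fast on one CPU).  Pass
    ``dtype=np.float64`` for full-precision scans.
    """
    if params.weights["embedding"].dtype == dtype:
        return params
    return ModelParams(params.config, {k: v.astype(dtype) for k, v in params.weights.items()})


def _score_tokens(params: ModelParams, tokens: np.ndarray) -> np.ndarray:
    """Score a (B, L) token matrix of equal-length sequences."""
    B, L = tokens.shape
    batch = EncodedBatch(
        token_matrix=tokens,
        lengths=np.full(B, L, dtype=np.int64),
        mask=np.ones((B, L)),
        permutation=np.arange(B),
        ids=[str(k) for k in range(B)],
    )
    return _forward_batch(params, batch, want_cache=False)["scores"]


def single_scan(
    params: ModelParams,
    sequence: str,
    vocab: Vocabulary = DEFAULT_VOCABULARY,
    batch_size: int = 1024,
    dtype: np.dtype = np.float32,
) -> tuple[float, np.ndarray]:
    """Exhaustive single-substitution scan.

    Returns (wildtype score, dS matrix of shape (L, 20)) with columns in
    :data:`AMINO_ACIDS` order; the wildtype column of each row is 0.
    Runs in single precision by default (see :func:`_cast_params`).
    """
    params = _cast_params(params, dtype)
    sequence = sanitize(sequence)
    L = len(sequence)
    if L == 0:
        raise ValueError("empty sequence")
    wt_tokens = vocab.encode(sequence)
    wt_score = float(_score_tokens(params, wt_tokens[None, :])[0])

    aa_idx = np.array([vocab.index_of(a) for a in AMINO_ACIDS])
    positions = np.repeat(np.arange(L), 20)
    subs = np.tile(aa_idx, L)
    delta = np.empty(L * 20)
    for start in range(0, L * 20, batch_size):
        pos = positions[start : start + batch_size]
        sub = subs[start : start + batch_size]
        toks = np.tile(wt_tokens, (pos.size, 1))
        toks[np.arange(pos.size), pos] = sub
        delta[start : start + pos.size] = _score_tokens(params, toks) - wt_score
    ds = delta.reshape(L, 20)
    # self-substitution leaves the sequence unchanged: force exact zeros
    wt_cols = np.array([AMINO_ACIDS.index(a) for a in sequence])
    ds[np.arange(L), wt_cols] = 0.0
    return wt_score, ds


def pair_count(L: int) -> int:
    """Number of tandem pairs in a full scan of a length-L sequence."""
    if L < 2:
        raise ValueError("need L >= 2")
    return (L * 20 * (L - 1) * 20) // 2


def pair_scan(
    params: ModelParams,
    sequence: str,
    vocab: Vocabulary = DEFAULT_VOCABULARY,
    batch_size: int = 2048,
    single: tuple[float, np.ndarray] | None = None,
    dtype: np.dtype = np.float32,
) -> Iterator[list[PairEffect]]:
    """Stream the exhaustive tandem-pair scan in batches of PairEffect.

    Enumerates every unordered pair of substitutions at distinct
    positions (i < j), 20 amino acids per position including the
    wildtype identity.  ``single`` may pass a precomputed
    :func:`single_scan` result to avoid recomputation.  Runs in single
    precision by default (see :func:`_cast_params`).
    """
    params = _cast_params(params, dtype)
    sequence = sanitize(sequence)
    L = len(sequence)
    if L < 2:
        raise ValueError("pair scan needs a sequence of length >= 2")
    wt_score, ds_single = (
        single if single is not None else single_scan(params, sequence, vocab, dtype=dtype)
    )
    wt_tokens = vocab.encode(sequence)
    aa_idx = np.array([vocab.index_of(a) for a in AMINO_ACIDS])

    buf_i: list[int] = []
    buf_j: list[int] = []
    buf_a: list[int] = []
    buf_b: list[int] = []

    def flush() -> list[PairEffect]:
        pi = np.array(buf_i)
        pj = np.array(buf_j)
        ai = np.array(buf_a)
        bj = np.array(buf_b)
        toks = np.tile(wt_tokens, (pi.size, 1))
        rows = np.arange(pi.size)
        toks[rows, pi] = aa_idx[ai]
        toks[rows, pj] = aa_idx[bj]
        ds_pair = _score_tokens(params, toks) - wt_score
        out = [
            PairEffect(
                i=int(pi[k]) + 1,
                j=int(pj[k]) + 1,
                aa_i=AMINO_ACIDS[ai[k]],
                aa_j=AMINO_ACIDS[bj[k]],
                delta_s_pair=float(ds_pair[k]),
                delta_s_single=float(ds_single[pi[k], ai[k]] + ds_single[pj[k], bj[k]]),
            )
            for k in rows
        ]
        buf_i.clear(), buf_j.clear(), buf_a.clear(), buf_b.clear()
        return out

    for i in range(L - 1):
        for j in range(i + 1, L):
            for a in range(20):
                for b in range(20):
                    buf_i.append(i)
                    buf_j.append(j)
                    buf_a.append(a)
                    buf_b.append(b)
                    if len(buf_i) >= batch_size:
                        yield flush()
    if buf_i:
        yield flush()


def synergy_map(pairs: Iterable[list[PairEffect] | PairEffect], L: int) -> SynergyMap:
    """Mean dE per position pair from a complete pair-scan stream."""
    total = np.zeros((L, L))
    count = np.zeros((L, L), dtype=np.int64)
    for item in pairs:
        batch = item if isinstance(item, list) else [item]
        for pe in batch:
            i, j = pe.i - 1, pe.j - 1
            total[i, j] += pe.delta_e
            count[i, j] += 1
    iu = np.triu_indices(L, k=1)
    if not np.all(count[iu] == 400):
        raise ValueError("incomplete pair stream: expected 400 substitution pairs per position pair")
    mat = np.full((L, L), np.nan)
    mat[iu] = total[iu] / 400.0
    mat[(iu[1], iu[0])] = mat[iu]
    return SynergyMap(matrix=mat)


def separation_profile(smap: SynergyMap) -> SeparationProfile:
    """Mean and median map entry per sequence separation d = |i - j|."""
    L = smap.length
    seps = np.arange(1, L)
    means = np.empty(L - 1)
    medians = np.empty(L - 1)
    for d in seps:
        diag = np.diagonal(smap.matrix, offset=d)
        means[d - 1] = diag.mean()
        medians[d - 1] = np.median(diag)
    return SeparationProfile(separations=seps, mean=means, median=medians)


def residue_distance_profile(
    structure_path: str | Path, chain_id: str
) -> SeparationProfile:
    """Mean/median C-beta distance (Angstrom) per sequence separation.

    Uses the C-beta atom of each standard residue (C-alpha for glycine);
    residues missing the required atom are skipped with a warning.
    Separation is counted over the chain's polymer residue order.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import is_aa

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(structure_path))
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model]:
        raise ValueError(f"chain {chain_id!r} not found in {structure_path}")
    chain = model[chain_id]
    coords: list[tuple[int, np.ndarray]] = []
    pos = 0
    for res in chain:
        if not is_aa(res, standard=True):
            continue
        pos += 1
        atom = "CA" if res.get_resname() == "GLY" else "CB"
        if atom in res:
            coords.append((pos, res[atom].coord.astype(float)))
        else:
            logger.warning("residue %s %s missing %s atom; skipped", res.get_resname(), res.id, atom)
    if len(coords) < 2:
        raise ValueError("fewer than two usable residues in chain")
    by_sep: dict[int, list[float]] = {}
    for x in range(len(coords)):
        for y in range(x + 1, len(coords)):
            d = coords[y][0] - coords[x][0]
            dist = float(np.linalg.norm(coords[y][1] - coords[x][1]))
            by_sep.setdefault(d, []).append(dist)
    seps = np.array(sorted(by_sep))
    return SeparationProfile(
        separations=seps,
        mean=np.array([np.mean(by_sep[d]) for d in seps]),
        median=np.array([np.median(by_sep[d]) for d in seps]),
    )


def correlate_synergy_distance(
    synergy: SeparationProfile, distance: SeparationProfile
) -> dict[str, float]:
    """Pearson and Spearman correlation of the two per-separation mean profiles.

    Profiles are matched on their shared separations; needs at least 3.
    """
    shared = np.intersect1d(synergy.separations, distance.separations)
    if shared.size < 3:
        raise ValueError("fewer than 3 shared separations")
    sx = synergy.mean[np.searchsorted(synergy.separations, shared)]
    dx = distance.mean[np.searchsorted(distance.separations, shared)]
    pr, pp = stats.pearsonr(sx, dx)
    sr, sp = stats.spearmanr(sx, dx)
    return {
        "pearson_r": float(pr),
        "pearson_p": float(pp),
        "spearman_r": float(sr),
        "spearman_p": float(sp),
        "n_separations": int(shared.size),
    }
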