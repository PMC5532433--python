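"""Position-specific profile models over the amino-acid alphabet.

A ProfileModel is a linear chain of match states built from a trusted seed
alignment: columns with fewer than 50% gaps become match states whose
emission scores are log-odds (base 2) of Laplace-smoothed column frequencies
against a uniform 1/20 background.  Scoring is local Viterbi over
match/insert/delete moves with affine gap penalties and free uniform
entry/exit into any match state, so the best-scoring contiguous stretch of
the profile is reported, floored at 0 bits for the empty path.  This mirrors
hmmsearch-style domain scoring without Plan7's loop states or E-value
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class ProfileError(ValueError):
    pass


@dataclass
class ProfileModel:
    """A profile of M match states with log-odds emissions (bits)."""

    name: str
    domain_tag: str
    match_log_odds: np.ndarray  # (M, 20) bits
    score_cutoff_bits: float
    background: np.ndarray = field(
        default_factory=lambda: np.full(20, 1.0 / 20.0)
    )
    gap_open_bits: float = 4.0
    gap_extend_bits: float = 1.0

    def __post_init__(self) -> None:
        self.match_log_odds = np.asarray(self.match_log_odds, dtype=float)
        if self.match_log_odds.ndim != 2 or self.match_log_odds.shape[1] != 20:
            raise ProfileError("match_log_odds must be (M, 20)")
        if self.match_log_odds.shape[0] < 1:
            raise ProfileError("profile needs at least one match state")
        if not np.isfinite(self.score_cutoff_bits):
            raise ProfileError("score cutoff must be finite")

    @property
    def n_states(self) -> int:
        return self.match_log_odds.shape[0]

    def consensus(self) -> str:
        """Highest-scoring residue at each match state."""
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.match_log_odds, axis=1))


def encode_protein(protein: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[a] for a in protein], dtype=np.int64)
    except KeyError as exc:
        raise ProfileError(f"illegal residue {exc.args[0]!r} in protein") from None


def build_profile(
    seed_alignment: list[SequenceRecord],
    domain_tag: str,
    cutoff_bits: float,
    name: str | None = None,
    pseudocount: float = 1.0,
    max_gap_fraction: float = 0.5,
) -> ProfileModel:
    """Build a ProfileModel from an aligned set of protein records.

    Columns with >= ``max_gap_fraction`` gap characters are dropped from the
    match states; emissions are ``log2(((count + pseudocount) / (n_obs + 20 *
    pseudocount)) / (1/20))`` where ``n_obs`` counts non-gap residues in the
    column.  Deterministic for a given alignment.
    """
    if len(seed_alignment) < 2:
        raise ProfileError("seed alignment needs >= 2 sequences")
    width = len(seed_alignment[0].sequence)
    for rec in seed_alignment:
        if len(rec.sequence) != width:
            raise ProfileError(
                f"ragged alignment: {rec.id!r} has length {len(rec.sequence)} != {width}"
            )
    n = len(seed_alignment)
    rows = []
    for col in range(width):
        residues = [rec.sequence[col] for rec in seed_alignment]
        gaps = sum(1 for r in residues if r in "-.")
        if gaps / n >= max_gap_fraction:
            continue
        counts = np.full(20, pseudocount)
        n_obs = 0
        for r in residues:
            if r in "-.":
                continue
            if r not in _AA_INDEX:
                raise ProfileError(f"illegal residue {r!r} in alignment column {col}")
            counts[_AA_INDEX[r]] += 1
            n_obs += 1
        freqs = counts / (n_obs + 20 * pseudocount)
        rows.append(np.log2(freqs * 20.0))
    if not rows:
        raise ProfileError("no match states: every column exceeded the gap fraction")
    return ProfileModel(
        name=name or f"profile_{domain_tag}",
        domain_tag=domain_tag,
        match_log_odds=np.vstack(rows),
        score_cutoff_bits=cutoff_bits,
    )


def score_sequence(profile: ProfileModel, protein: str) -> float:
    """Best local profile-alignment score of ``protein``, in bits.

    Viterbi over match (consumes one residue, advances one state), insert
    (consumes a residue between match states, affine penalty) and delete
    (skips match states, affine penalty).  Entry into and exit from any match
    state is free; the empty path scores 0, so scores are never negative.
    """
    if not protein:
        raise ProfileError("empty protein")
    x = encode_protein(protein)
    emis = profile.match_log_odds[:, x].T  # (L, M): emission of residue i at state j
    L, M = emis.shape
    go, ge = profile.gap_open_bits, profile.gap_extend_bits

    neg = -np.inf
    idx = np.arange(M, dtype=float)
    m_prev = np.full(M, neg)
    i_prev = np.full(M, neg)
    d_prev = np.full(M, neg)
    best = 0.0
    for i in range(L):
        # best predecessor ending at state j-1 on the previous residue
        prev = np.maximum(np.maximum(m_prev, i_prev), d_prev)
        enter = np.zeros(M)  # free local entry at any state
        enter[1:] = np.maximum(enter[1:], prev[:-1])
        m_cur = emis[i] + enter
        # insert after state j: open from match, or extend an open insert
        i_cur = np.maximum(m_prev - go, i_prev - ge)
        # delete chain within this row: D[j] = max_{k<j} M[j'] - go - (j-1-k)*ge
        d_cur = np.full(M, neg)
        if M > 1:
            running = np.maximum.accumulate(m_cur + idx * ge)
            d_cur[1:] = running[:-1] - go - (idx[1:] - 1.0) * ge
        row_best = m_cur.max()
        if row_best > best:
            best = float(row_best)
        m_prev, i_prev, d_prev = m_cur, i_cur, d_cur
    return best
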