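"""Kingdom-specific profile HMMs and two-helix bHLH identification.

For each Kingdom, two profile HMMs are trained — one on the Helix 1 columns
(sites 14-28) and one on Helix 2 (sites 50-64) of the Kingdom's alignment.
A query protein is identified as bHLH by a Kingdom pair if and only if a
Helix 1 hit completely precedes a Helix 2 hit and both hit scores exceed
the threshold (default 0.1 bits, strict).

The scoring engine is a self-contained profile HMM: match states with
position-specific emissions, insert states emitting the background
distribution, and delete states.  Alignment is local in the query (it may
begin and end at any query position, for free) but global in the model:
every helix column must be traversed, and columns skipped at either end
are charged as delete transitions.  This matters for specificity — a helix
is only a hit when essentially the whole helix profile is matched, so
short spurious residue runs in non-bHLH sequence score far below the
threshold.  Scores are log2-odds against the background distribution, in
bits; transition probabilities contribute log2 penalties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, GAP
from .coordinates import DEFAULT_COORDINATES, CoordinateMap

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Default transition priors; helices are short and nearly gap-free in
#: training data, so match self-continuation dominates.
DEFAULT_TRANSITIONS = {
    "mm": 0.95,
    "mi": 0.025,
    "md": 0.025,
    "ii": 0.3,
    "dd": 0.3,
}


@dataclass
class HmmHit:
    """A local alignment of a query against a profile HMM."""

    start: int  # 1-based inclusive on the query
    end: int
    score: float  # bits, log2 odds vs background
    match_columns: dict[int, int] = field(default_factory=dict)  # model col -> query pos

    def shifted(self, offset: int) -> "HmmHit":
        return HmmHit(
            self.start + offset,
            self.end + offset,
            self.score,
            {c: q + offset for c, q in self.match_columns.items()},
        )


@dataclass
class BhlhCall:
    """Outcome of the ordered two-helix identification rule."""

    query_id: str
    kingdom: str
    helix1: HmmHit | None
    helix2: HmmHit | None
    identified: bool


class ProfileHMM:
    """Position-specific profile of one helix sub-alignment.

    Parameters
    ----------
    match_emissions : (L, 20) array
        Per-column emission probabilities over the canonical residues.
    background : (20,) array
        Background residue distribution (also the insert emission).
    transitions : dict
        Keys ``mm``/``mi``/``md`` map to length-L arrays (outgoing from
        match column j; the last column's values are unused because exit
        is free); ``ii`` and ``dd`` are scalars.
    """

    def __init__(
        self,
        match_emissions: np.ndarray,
        background: np.ndarray,
        transitions: Mapping[str, np.ndarray | float],
    ):
        self.match_emissions = np.asarray(match_emissions, dtype=float)
        self.background = np.asarray(background, dtype=float)
        self.L = self.match_emissions.shape[0]
        self.t_mm = np.broadcast_to(np.asarray(transitions["mm"], float), (self.L,)).copy()
        self.t_mi = np.broadcast_to(np.asarray(transitions["mi"], float), (self.L,)).copy()
        self.t_md = np.broadcast_to(np.asarray(transitions["md"], float), (self.L,)).copy()
        self.t_ii = float(transitions["ii"])
        self.t_dd = float(transitions["dd"])
        self._validate()
        with np.errstate(divide="ignore"):
            self._lemit = np.log2(self.match_emissions) - np.log2(self.background)
            self._l_mm = np.log2(self.t_mm)
            self._l_mi = np.log2(self.t_mi)
            self._l_md = np.log2(self.t_md)
            self._l_ii = np.log2(self.t_ii) if self.t_ii > 0 else -np.inf
            self._l_im = np.log2(1 - self.t_ii) if self.t_ii < 1 else -np.inf
            self._l_dd = np.log2(self.t_dd) if self.t_dd > 0 else -np.inf
            self._l_dm = np.log2(1 - self.t_dd) if self.t_dd < 1 else -np.inf
        # model-global entry/exit: skipped leading/trailing columns cost
        # a delete chain (begin -> D1 ... D(j-1) -> Mj; Mj -> Dj+1 ... DL -> end)
        L = self.L
        self._entry = np.full(L, 0.0)
        self._exit = np.full(L, 0.0)
        for j in range(1, L):
            self._entry[j] = self._l_md[0] + (j - 1) * self._l_dd + self._l_dm
        for j in range(L - 1):
            self._exit[j] = self._l_md[j] + (L - 2 - j) * self._l_dd

    def _validate(self) -> None:
        if self.match_emissions.shape != (self.L, 20):
            raise ValueError("match_emissions must be (L, 20)")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if (self.background <= 0).any():
            raise ValueError("background must be strictly positive")
        out = self.t_mm + self.t_mi + self.t_md
        if not np.allclose(out, 1.0, atol=1e-9):
            raise ValueError("match outgoing transitions must sum to 1")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_alignment(
        cls,
        columns: pd.DataFrame,
        pseudocount: float = 1.0,
        background: np.ndarray | str | None = None,
        transition_priors: Mapping[str, float] | None = None,
    ) -> "ProfileHMM":
        """Build from a helix sub-alignment (rows = sequences, columns =
        helix sites, residues or GAP).

        Match emissions at column j are ``(count_a + pc * bg_a) /
        (n_j + pc)`` with n_j the non-gap count.  The match->delete
        probability into column j+1 blends that column's gap fraction with
        the prior at weight ``pseudocount``.
        """
        if len(columns) == 0:
            raise ValueError("empty helix alignment")
        priors = dict(DEFAULT_TRANSITIONS)
        if transition_priors:
            priors.update(transition_priors)
        R = columns.to_numpy(dtype=object)
        n, L = R.shape
        counts = np.zeros((L, 20))
        gaps = np.zeros(L)
        for j in range(L):
            for r in R[:, j]:
                if r in _AA_INDEX:
                    counts[j, _AA_INDEX[r]] += 1
                else:
                    gaps[j] += 1
        if background is None:
            # pooled training frequencies, Laplace-smoothed so log-odds stay finite
            pooled = counts.sum(axis=0) + 0.5
            bg = pooled / pooled.sum()
        elif isinstance(background, str):
            if background != "uniform":
                raise ValueError(f"unknown background {background!r}")
            bg = np.full(20, 1 / 20)
        else:
            bg = np.asarray(background, dtype=float)
        n_obs = counts.sum(axis=1)
        if pseudocount == 0 and (n_obs == 0).any():
            raise ValueError("all-gap column with zero pseudocount")
        emissions = (counts + pseudocount * bg) / (n_obs + pseudocount)[:, None]
        # match->delete into column j+1 from that column's gap fraction
        t_md = np.full(L, priors["md"])
        denom = n + pseudocount
        for j in range(L - 1):
            t_md[j] = (gaps[j + 1] + pseudocount * priors["md"]) / denom
        t_mi = np.full(L, priors["mi"])
        t_mm = 1.0 - t_mi - t_md
        return cls(
            emissions,
            bg,
            {"mm": t_mm, "mi": t_mi, "md": t_md, "ii": priors["ii"], "dd": priors["dd"]},
        )

    # -- scoring -----------------------------------------------------------

    def emission_scores(self, query: str) -> np.ndarray:
        """(L, len(query)) match emission log-odds; unknown residues score
        0 (treated as background)."""
        n = len(query)
        E = np.zeros((self.L, n))
        for i, ch in enumerate(query):
            k = _AA_INDEX.get(ch)
            if k is not None:
                E[:, i] = self._lemit[:, k]
        return E

    def viterbi(self, query: str) -> HmmHit | None:
        """Best query-local, model-global alignment; None when no alignment
        scores above 0 bits."""
        n = len(query)
        if n == 0:
            return None
        L = self.L
        E = self.emission_scores(query)
        NEG = -np.inf
        M = np.full((L, n), NEG)
        I = np.full((L, n), NEG)
        D = np.full((L, n), NEG)
        for i in range(n):
            if i == 0:
                M[:, 0] = E[:, 0] + self._entry
            else:
                prev_m = np.concatenate(([NEG], M[:-1, i - 1] + self._l_mm[:-1]))
                prev_i = np.concatenate(([NEG], I[:-1, i - 1] + self._l_im))
                prev_d = np.concatenate(([NEG], D[:-1, i - 1] + self._l_dm))
                best_prev = np.maximum.reduce([prev_m, prev_i, prev_d])
                M[:, i] = E[:, i] + np.maximum(best_prev, self._entry)
                I[:, i] = np.maximum(M[:, i - 1] + self._l_mi, I[:, i - 1] + self._l_ii)
            # delete chain within query position i
            for j in range(1, L):
                D[j, i] = max(M[j - 1, i] + self._l_md[j - 1], D[j - 1, i] + self._l_dd)
        S = M + self._exit[:, None]
        best = float(S.max())
        if not best > 0:
            return None
        j, i = np.unravel_index(int(S.argmax()), S.shape)
        cols = self._traceback(int(j), int(i), M, I, D, E)
        qpos = list(cols.values())
        return HmmHit(start=min(qpos), end=i + 1, score=best, match_columns=cols)

    def _traceback(
        self, j: int, i: int, M: np.ndarray, I: np.ndarray, D: np.ndarray, E: np.ndarray
    ) -> dict[int, int]:
        """Recover (model column -> query position) match pairs, 1-based."""
        cols: dict[int, int] = {}
        state = "M"
        tol = 1e-9
        while True:
            if state == "M":
                cols[j + 1] = i + 1
                rest = M[j, i] - E[j, i]
                if i > 0 and j > 0:
                    if abs(rest - (M[j - 1, i - 1] + self._l_mm[j - 1])) <= tol:
                        j, i = j - 1, i - 1
                        continue
                    if abs(rest - (I[j - 1, i - 1] + self._l_im)) <= tol:
                        j, i, state = j - 1, i - 1, "I"
                        continue
                    if abs(rest - (D[j - 1, i - 1] + self._l_dm)) <= tol:
                        j, i, state = j - 1, i - 1, "D"
                        continue
                return cols  # model entry (free at column 1, delete chain above it)
            elif state == "I":
                if abs(I[j, i] - (M[j, i - 1] + self._l_mi[j])) <= tol:
                    i, state = i - 1, "M"
                else:
                    i = i - 1
            else:  # D
                if j > 0 and abs(D[j, i] - (D[j - 1, i] + self._l_dd)) <= tol:
                    j = j - 1
                else:
                    j, state = j - 1, "M"

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "match_emissions": self.match_emissions.tolist(),
            "background": self.background.tolist(),
            "transitions": {
                "mm": self.t_mm.tolist(),
                "mi": self.t_mi.tolist(),
                "md": self.t_md.tolist(),
                "ii": self.t_ii,
                "dd": self.t_dd,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileHMM":
        return cls(np.array(d["match_emissions"]), np.array(d["background"]), d["transitions"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "ProfileHMM":
        return cls.from_dict(json.loads(Path(path).read_text()))


def viterbi_hit(hmm: ProfileHMM, query: str) -> HmmHit | None:
    return hmm.viterbi(query)


def identify_bhlh(
    query: str,
    helix1_hmm: ProfileHMM,
    helix2_hmm: ProfileHMM,
    threshold: float = 0.1,
    query_id: str = "",
    kingdom: str = "",
) -> BhlhCall:
    """Apply the ordered two-helix rule: identified iff a Helix 1 hit
    completely precedes a Helix 2 hit and both scores exceed ``threshold``
    (strict).  When the unconstrained best Helix 2 hit overlaps or precedes
    Helix 1, Helix 2 is re-searched downstream of the Helix 1 hit."""
    h1 = helix1_hmm.viterbi(query)
    h2 = helix2_hmm.viterbi(query)
    if h1 is not None and h2 is not None and h2.start <= h1.end:
        h2 = None
    if h1 is not None and h2 is None:
        tail = helix2_hmm.viterbi(query[h1.end:])
        if tail is not None:
            h2 = tail.shifted(h1.end)
    identified = (
        h1 is not None
        and h2 is not None
        and h1.end < h2.start
        and h1.score > threshold
        and h2.score > threshold
    )
    return BhlhCall(query_id=query_id, kingdom=kingdom, helix1=h1, helix2=h2, identified=bool(identified))


def extract_domain(
    call: BhlhCall, query: str, coordinates: CoordinateMap = DEFAULT_COORDINATES
) -> dict[int, str]:
    """Map an identified call onto the fixed site numbering.

    Helix hit match columns map to the helix sites; the residues
    immediately preceding the Helix 1 hit fill the basic region (gap-padded
    on the left when fewer are available); inter-helix residues fill the
    loop sites, truncated when the loop is longer than the site range.
    """
    if not call.identified:
        raise ValueError("cannot extract a domain from an unidentified call")
    record: dict[int, str] = {s: GAP for s in coordinates.fixed_sites}
    h1_sites = coordinates.helix1_sites
    h2_sites = coordinates.helix2_sites
    for col, qpos in call.helix1.match_columns.items():
        record[h1_sites[col - 1]] = query[qpos - 1]
    for col, qpos in call.helix2.match_columns.items():
        record[h2_sites[col - 1]] = query[qpos - 1]
    basic_sites = coordinates.basic_sites
    avail = query[max(0, call.helix1.start - 1 - len(basic_sites)) : call.helix1.start - 1]
    for site, ch in zip(reversed(basic_sites), reversed(avail)):
        record[site] = ch
    loop = query[call.helix1.end : call.helix2.start - 1]
    for site, ch in zip(coordinates.loop_sites, loop):
        record[site] = ch
    return record


def scan_proteome(
    sequences: Mapping[str, str] | Iterable,
    kingdom_hmms: Mapping[str, tuple[ProfileHMM, ProfileHMM]],
    threshold: float = 0.1,
) -> tuple[pd.DataFrame, dict]:
    """Scan every sequence with every Kingdom's helix pair.

    Returns a calls table (one row per sequence x kingdom) and an overlap
    summary with per-kingdom identified sets, the number identified by
    exactly one kingdom, and Venn-style region counts.
    """
    if not kingdom_hmms:
        raise ValueError("need at least one kingdom HMM pair")
    if not isinstance(sequences, Mapping):
        sequences = {rec.id: str(rec.seq) for rec in sequences}
    rows = []
    identified: dict[str, set[str]] = {k: set() for k in kingdom_hmms}
    for qid, seq in sequences.items():
        for kingdom, (h1, h2) in kingdom_hmms.items():
            call = identify_bhlh(seq, h1, h2, threshold, query_id=qid, kingdom=kingdom)
            rows.append(
                {
                    "query_id": qid,
                    "kingdom": kingdom,
                    "identified": call.identified,
                    "helix1_start": call.helix1.start if call.helix1 else None,
                    "helix1_end": call.helix1.end if call.helix1 else None,
                    "helix1_score": call.helix1.score if call.helix1 else None,
                    "helix2_start": call.helix2.start if call.helix2 else None,
                    "helix2_end": call.helix2.end if call.helix2 else None,
                    "helix2_score": call.helix2.score if call.helix2 else None,
                }
            )
            if call.identified:
                identified[kingdom].add(qid)
    calls = pd.DataFrame(rows)
    all_ids = set().union(*identified.values()) if identified else set()
    membership: dict[str, int] = {}
    for qid in all_ids:
        membership[qid] = sum(qid in s for s in identified.values())
    summary = {
        "per_kingdom": {k: sorted(s) for k, s in identified.items()},
        "n_identified_total": len(all_ids),
        "n_unique_assignment": sum(1 for v in membership.values() if v == 1),
        "n_multi_kingdom": sum(1 for v in membership.values() if v > 1),
    }
    return calls, summary


def build_kingdom_hmms(
    alignment,
    pseudocount: float = 1.0,
    background: np.ndarray | str | None = None,
    transition_priors: Mapping[str, float] | None = None,
) -> dict[str, tuple[ProfileHMM, ProfileHMM]]:
    """Per-Kingdom (Helix 1, Helix 2) HMM pairs from a labeled alignment."""
    if alignment.kingdom is None:
        raise ValueError("alignment must carry Kingdom labels")
    coords = alignment.coordinates
    pairs: dict[str, tuple[ProfileHMM, ProfileHMM]] = {}
    for kingdom in sorted(alignment.kingdom.dropna().unique()):
        ids = alignment.kingdom[alignment.kingdom == kingdom].index
        sub = alignment.residues.loc[ids]
        h1 = ProfileHMM.from_alignment(
            sub[coords.helix1_sites], pseudocount, background, transition_priors
        )
        h2 = ProfileHMM.from_alignment(
            sub[coords.helix2_sites], pseudocount, background, transition_priors
        )
        pairs[str(kingdom)] = (h1, h2)
    return pairs


def load_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs
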