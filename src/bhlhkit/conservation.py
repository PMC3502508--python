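"""Per-site conservation analytics for enumerated bHLH alignments.

Three views of conservation are computed per fixed site:

* normalized group entropy — Boltzmann-Shannon entropy over eight
  physicochemical residue groups, scaled to [0, 1] by its maximum
  (log of the number of groups).  0 = perfectly conserved group,
  1 = uniform over groups.
* sequence-logo heights — information content R = log2(20) - H20 in bits,
  apportioned per residue as p_a * R.
* 50-10 consensus — a site is constrained iff its top residue exceeds 50%
  frequency (strict); then every residue above 10% (strict) is listed,
  primary residue first.

Gaps are excluded from frequency denominators: consensus percentages are
residue concentrations among observed residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, EnumeratedAlignment

#: Eight physicochemical groups partitioning the 20 amino acids:
#: acidic, basic, aromatic, aliphatic, aminic, hydroxylated, Cys, Pro.
DEFAULT_GROUPS: dict[str, str] = {
    "acidic": "DE",
    "basic": "HKR",
    "aromatic": "FWY",
    "aliphatic": "AGILMV",
    "aminic": "NQ",
    "hydroxylated": "ST",
    "cysteine": "C",
    "proline": "P",
}


def _validate_grouping(groups: dict[str, str]) -> dict[str, str]:
    members = "".join(groups.values())
    if sorted(members) != sorted(AMINO_ACIDS):
        raise ValueError("groups must partition the 20 amino acids")
    return groups


@dataclass
class SiteFrequencies:
    """Residue counts and relative frequencies at one site (gaps excluded)."""

    site: int
    counts: pd.Series
    n_observed: int

    @property
    def frequencies(self) -> pd.Series:
        if self.n_observed == 0:
            return self.counts.astype(float)
        return self.counts / self.n_observed


def site_frequencies(alignment: EnumeratedAlignment, site: int) -> SiteFrequencies:
    if site not in alignment.coordinates.fixed_sites:
        raise ValueError(f"site {site} outside the fixed coordinate map")
    col = alignment.residues[site]
    observed = col[col.isin(list(AMINO_ACIDS))]
    counts = observed.value_counts().astype(int)
    return SiteFrequencies(site=site, counts=counts, n_observed=int(len(observed)))


def normalized_group_entropy(
    freqs: SiteFrequencies, groups: dict[str, str] | None = None
) -> float:
    """Group entropy scaled to [0, 1]; NaN when no residues are observed.

    H = -sum_g p_g ln p_g over group frequencies, divided by ln(n_groups).
    The log base cancels in the ratio.
    """
    groups = _validate_grouping(groups or DEFAULT_GROUPS)
    if freqs.n_observed == 0:
        return float("nan")
    p = freqs.frequencies
    h = 0.0
    for members in groups.values():
        pg = float(p.reindex(list(members)).fillna(0.0).sum())
        if pg > 0:
            h -= pg * math.log(pg)
    return h / math.log(len(groups))


def logo_bits(freqs: SiteFrequencies) -> pd.Series:
    """Per-residue logo heights in bits: height(a) = p_a * (log2 20 - H20)."""
    if freqs.n_observed == 0:
        return pd.Series(dtype=float)
    p = freqs.frequencies
    h20 = float(-(p * np.log2(p)).sum())
    r = math.log2(20) - h20
    return (p * r).sort_values(ascending=False)


def information_bits(freqs: SiteFrequencies) -> float:
    """Site information content R = log2(20) - H20 in bits."""
    heights = logo_bits(freqs)
    return float(heights.sum()) if len(heights) else float("nan")


def consensus_50_10(freqs: SiteFrequencies) -> list[str] | None:
    """Residues at a constrained site under the 50-10 rule, or None.

    The top residue must exceed 0.5 (strict); secondary residues must
    exceed 0.1 (strict).  The primary residue is listed first, then
    secondaries by decreasing frequency.
    """
    if freqs.n_observed == 0:
        return None
    p = freqs.frequencies.sort_values(ascending=False, kind="stable")
    if float(p.iloc[0]) <= 0.5:
        return None
    out = [str(p.index[0])]
    for res, val in p.iloc[1:].items():
        if float(val) > 0.1:
            out.append(str(res))
    return out


def conservation_profile(
    alignment: EnumeratedAlignment, groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-site table: n_observed, normalized group entropy, information
    (bits), and 50-10 consensus string ('.' when unconstrained)."""
    rows = []
    for site in alignment.coordinates.fixed_sites:
        f = site_frequencies(alignment, site)
        cons = consensus_50_10(f)
        rows.append(
            {
                "site": site,
                "n_observed": f.n_observed,
                "group_entropy": normalized_group_entropy(f, groups),
                "information_bits": information_bits(f),
                "consensus": "".join(cons) if cons else ".",
            }
        )
    return pd.DataFrame(rows).set_index("site")


def logo_matrix(alignment: EnumeratedAlignment) -> pd.DataFrame:
    """Sites x residues matrix of logo heights (bits), for logo plotters."""
    rows = {}
    for site in alignment.coordinates.fixed_sites:
        rows[site] = logo_bits(site_frequencies(alignment, site))
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(AMINO_ACIDS)
    )
    df.index.name = "site"
    return df.fillna(0.0)


def consensus_string(alignment: EnumeratedAlignment) -> str:
    """Compact 50-10 consensus: primary residue, brackets for secondaries."""
    parts = []
    for site in alignment.coordinates.fixed_sites:
        cons = consensus_50_10(site_frequencies(alignment, site))
        if cons is None:
            parts.append(".")
        elif len(cons) == 1:
            parts.append(cons[0])
        else:
            parts.append(cons[0] + "[" + "".join(cons[1:]) + "]")
    return "".join(parts)
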