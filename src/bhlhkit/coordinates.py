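"""Fixed site coordinate system of the bHLH domain.

The domain is tripartite: a DNA-contacting basic region, two dimerization
helices, and a variable-length loop between them.  Sites are numbered on a
fixed scheme in which the basic region and Helix 1 occupy sites 1-28, the
loop occupies sites 29-49, and Helix 2 occupies sites 50-64.  Because the
loop varies in length between sequences, only the 43 basic/helix sites are
used as model variables; loop residues may be carried along but never enter
any numeric dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class CoordinateMap:
    """Subdomain boundaries on the fixed bHLH site numbering.

    Attributes
    ----------
    basic, helix1, loop, helix2 : tuple of (int, int)
        Inclusive 1-based site ranges.  Defaults: basic 1-13, Helix 1
        14-28, loop 29-49, Helix 2 50-64.
    """

    basic: tuple[int, int] = (1, 13)
    helix1: tuple[int, int] = (14, 28)
    loop: tuple[int, int] = (29, 49)
    helix2: tuple[int, int] = (50, 64)

    def __post_init__(self) -> None:
        ranges = [self.basic, self.helix1, self.loop, self.helix2]
        for lo, hi in ranges:
            if lo > hi:
                raise ValueError(f"empty subdomain range ({lo}, {hi})")
        flat = [x for r in ranges for x in r]
        if flat != sorted(flat) or len(set(self.fixed_sites)) != len(self.fixed_sites):
            raise ValueError("subdomain ranges must be disjoint and ordered")

    @property
    def fixed_sites(self) -> list[int]:
        """Sites that enter numeric datasets (basic + both helices)."""
        return (
            list(range(self.basic[0], self.basic[1] + 1))
            + list(range(self.helix1[0], self.helix1[1] + 1))
            + list(range(self.helix2[0], self.helix2[1] + 1))
        )

    @property
    def loop_sites(self) -> list[int]:
        return list(range(self.loop[0], self.loop[1] + 1))

    @property
    def basic_sites(self) -> list[int]:
        return list(range(self.basic[0], self.basic[1] + 1))

    @property
    def helix1_sites(self) -> list[int]:
        return list(range(self.helix1[0], self.helix1[1] + 1))

    @property
    def helix2_sites(self) -> list[int]:
        return list(range(self.helix2[0], self.helix2[1] + 1))

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_sites)


DEFAULT_COORDINATES = CoordinateMap()
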