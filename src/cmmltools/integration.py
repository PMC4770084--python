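"""Integration of DMR-annotated genes with differential-expression lists.

Differential-expression calling itself is upstream (the lists are
inputs); this module computes the Venn overlap between DMR genes and
up-/down-regulated genes, and the pairwise chi-squared comparison of DE
proportions between treatment arms over a common tested-gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, Mapping, Sequence, Set

import pandas as pd
from scipy.stats import chi2_contingency


@dataclass
class DEGeneList:
    """Up/down differentially expressed gene symbols for one arm."""

    arm: str
    up: set = field(default_factory=set)
    down: set = field(default_factory=set)
    universe_size: int = 24_563

    def __post_init__(self) -> None:
        self.up = {str(g).upper() for g in self.up}
        self.down = {str(g).upper() for g in self.down}
        if self.up & self.down:
            raise ValueError(f"{self.arm}: genes in both up and down lists")
        if len(self.up) + len(self.down) > self.universe_size:
            raise ValueError(f"{self.arm}: DE genes exceed the universe")

    @property
    def n_de(self) -> int:
        return len(self.up) + len(self.down)


def overlap_dmr_expression(
    dmr_genes: Iterable[str], de: DEGeneList
) -> Dict[str, int]:
    """Venn counts between DMR-annotated genes and up/down DE genes."""
    dmr = {str(g).upper() for g in dmr_genes}
    return {
        "dmr_only": len(dmr - de.up - de.down),
        "up_only": len(de.up - dmr),
        "down_only": len(de.down - dmr),
        "dmr_and_up": len(dmr & de.up),
        "dmr_and_down": len(dmr & de.down),
        "n_dmr_genes": len(dmr),
        "n_up": len(de.up),
        "n_down": len(de.down),
    }


def compare_de_proportions(lists: Sequence[DEGeneList]) -> pd.DataFrame:
    """Pairwise chi-squared tests of DE-gene proportions between arms.

    Each pair is compared on a 2x2 (DE, not DE) x (arm A, arm B) table
    without continuity correction.  Two arms with zero DE genes each are
    reported as chi2 = 0, p = 1.
    """
    rows = []
    for a, b in combinations(lists, 2):
        if a.n_de > a.universe_size or b.n_de > b.universe_size:
            raise ValueError("DE count exceeds universe")
        table = [
            [a.n_de, a.universe_size - a.n_de],
            [b.n_de, b.universe_size - b.n_de],
        ]
        if a.n_de == 0 and b.n_de == 0:
            chi2, p = 0.0, 1.0
        else:
            chi2, p = chi2_contingency(table, correction=False)[:2]
        rows.append(
            {
                "arm_a": a.arm, "arm_b": b.arm,
                "de_a": a.n_de, "de_b": b.n_de,
                "universe_a": a.universe_size, "universe_b": b.universe_size,
                "chi2": float(chi2), "p": float(p),
            }
        )
    return pd.DataFrame(rows)
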