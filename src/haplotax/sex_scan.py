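"""Sex-biased expressed genes inside designated nonhomologous Z/W regions.

Expression is a genes x (tissue, sex) table (TPM scale).  A gene located in
one of the nonhomologous regions is called sex-biased in a tissue when it is
on (>= tau_on) in one sex and off (<= tau_off) in the other.  With no
replicates modelled, this is a thresholded contrast, not a differential
expression test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from haplotax.io_formats import GenomeInterval

TISSUES = ("root", "leaf", "bark", "flower")
SEXES = ("female", "male")


@dataclass(frozen=True)
class SexBiasCall:
    gene: str
    direction: str  # 'female-biased' | 'male-biased'
    on_value: float
    off_value: float


def sex_biased_genes(
    expr: pd.DataFrame,
    regions: Sequence[GenomeInterval],
    positions: Mapping[str, tuple[str, int]],
    tau_on: float = 1.0,
    tau_off: float = 0.1,
    tissue: str = "flower",
) -> list[SexBiasCall]:
    """Genes inside the regions with on/off expression between the sexes.

    expr must have a 2-level column index (tissue, sex) with sexes
    'female'/'male'.  A gene is female-biased when
    expr[tissue, female] >= tau_on and expr[tissue, male] <= tau_off
    (and symmetrically male-biased).  Genes outside every region are
    ignored regardless of their expression.
    """
    if tissue not in expr.columns.get_level_values(0):
        raise ValueError(f"unknown tissue label {tissue!r}")
    female = expr[(tissue, "female")]
    male = expr[(tissue, "male")]

    calls: list[SexBiasCall] = []
    for gene in expr.index:
        if gene not in positions:
            raise ValueError(f"gene {gene!r} has no genomic position")
        chrom, pos = positions[gene]
        if not any(r.contains_point(chrom, pos) for r in regions):
            continue
        f, m = float(female[gene]), float(male[gene])
        if f >= tau_on and m <= tau_off:
            calls.append(SexBiasCall(gene, "female-biased", f, m))
        elif m >= tau_on and f <= tau_off:
            calls.append(SexBiasCall(gene, "male-biased", m, f))
    return calls


__all__ = ["SexBiasCall", "sex_biased_genes", "TISSUES", "SEXES"]
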