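"""Cross-module integration: parent-of-origin H3K4me3 status in zygotes,
PEG x ChIP gene-set intersection, transient-PEG classification from joint
allelic-expression / H3K4me3 trajectories, and ERV proximity annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .config import ZGA_STAGES
from .genome import GenomeModel
from .peaks import Peak

#: allelic-expression band (in percent paternal) treated as biallelic
BIALLELIC_BAND = (35.0, 65.0)
#: minimum informative SNPs in a counting region for a "traceable" gene
MIN_TRACEABLE_SNPS = 3
#: loss stages within this many positions of each other count as coincident
COINCIDENCE_SLACK = 1


@dataclass
class IntegrationRecord:
    gene_id: str
    peg_status: str  # "candidate" | "confirmed" | "not-PEG"
    sperm_h3k4me3: bool
    zygote_paternal_h3k4me3: bool
    has_promoter_snps: bool
    validated_ap: bool
    expressed_pre_zga: bool
    carryover_confounded: bool
    transient: str  # "transient" | "stable" | "inconclusive"
    expression_loss_stage: str | None
    chip_loss_stage: str | None
    coincident_loss: bool
    trend_pvalue: float | None
    erv_families: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.transient == "transient":
            if self.peg_status != "confirmed" or not self.expression_loss_stage:
                raise ValueError("transient calls require a confirmed PEG with a loss stage")


def _overlaps(peak: Peak, region: tuple[str, int, int]) -> bool:
    chrom, start, end = region
    return peak.chrom == chrom and peak.start < end and peak.end > start


def zygote_parental_status(
    paternal_peaks: Sequence[Peak],
    maternal_peaks: Sequence[Peak],
    oocyte_peaks: Sequence[Peak],
    gene_regions: Mapping[str, tuple[str, int, int]],
) -> dict[str, bool]:
    """Per gene: True iff a paternal-pronucleus peak overlaps the gene's
    promoter/sperm-retained region while neither the maternal pronucleus
    nor the oocyte has a peak there (a parent-of-origin-specific
    H3K4me3 state at the zygote stage)."""
    out = {}
    for gene_id, region in gene_regions.items():
        pat = any(_overlaps(p, region) for p in paternal_peaks)
        mat = any(_overlaps(p, region) for p in maternal_peaks)
        ooc = any(_overlaps(p, region) for p in oocyte_peaks)
        out[gene_id] = bool(pat and not mat and not ooc)
    return out


def intersect_peg_chip(peg_set: set, chip_gene_set: set) -> dict:
    """|PEG ∩ ChIP|, |PEG| and their ratio, plus a per-gene membership table."""
    peg = set(peg_set)
    chip = set(chip_gene_set)
    inter = peg & chip
    table = pd.DataFrame(
        {
            "peg": [g in peg for g in sorted(peg | chip)],
            "chip": [g in chip for g in sorted(peg | chip)],
        },
        index=pd.Index(sorted(peg | chip), name="gene_id"),
    )
    return {
        "n_overlap": len(inter),
        "n_peg": len(peg),
        "fraction": (len(inter) / len(peg)) if peg else float("nan"),
        "table": table,
    }


def classify_transient(
    gene_id: str,
    expression_calls: Mapping[str, str],
    chip_directions: Mapping[str, str],
    stage_order: Sequence[str],
    zga_stages: Sequence[str] = ZGA_STAGES,
) -> dict:
    """Classify a confirmed PEG as transient / stable / inconclusive.

    ``expression_calls`` maps stage -> {"paternal", "biallelic", "other"}
    (biallelic = per-stage DE fails the paternal call AND the allelic
    ratio sits inside the 50±15% band).  A gene is transient when it is
    paternally expressed at >= 1 ZGA stage and biallelic at a later
    assayed stage; the expression loss stage is the first biallelic
    stage after the last paternal stage.  The first stage at which the
    H3K4me3 enrichment stops being called paternal (after having been
    paternal) is reported for loss-coincidence.
    """
    order = [s for s in stage_order if s in expression_calls]
    if len(order) < 3:
        return {
            "gene_id": gene_id,
            "class": "inconclusive",
            "expression_loss_stage": None,
            "chip_loss_stage": _chip_loss_stage(chip_directions, stage_order),
            "coincident": False,
        }
    paternal_stages = [s for s in order if expression_calls[s] == "paternal" and s in zga_stages]
    chip_loss = _chip_loss_stage(chip_directions, stage_order)
    if not paternal_stages:
        return {
            "gene_id": gene_id,
            "class": "inconclusive",
            "expression_loss_stage": None,
            "chip_loss_stage": chip_loss,
            "coincident": False,
        }
    last_pat = max(order.index(s) for s in paternal_stages
                   if expression_calls[s] == "paternal")
    # extend through later paternal stages outside the ZGA window
    for i, s in enumerate(order):
        if expression_calls[s] == "paternal":
            last_pat = max(last_pat, i)
    loss = next((s for s in order[last_pat + 1:] if expression_calls[s] == "biallelic"), None)
    if loss is None:
        cls = "stable"
    else:
        cls = "transient"
    coincident = False
    if loss is not None and chip_loss is not None:
        full = list(stage_order)
        if loss in full and chip_loss in full:
            coincident = abs(full.index(loss) - full.index(chip_loss)) <= COINCIDENCE_SLACK
    return {
        "gene_id": gene_id,
        "class": cls,
        "expression_loss_stage": loss,
        "chip_loss_stage": chip_loss,
        "coincident": coincident,
    }


def _chip_loss_stage(chip_directions: Mapping[str, str], stage_order: Sequence[str]) -> str | None:
    """First stage at which a previously paternal H3K4me3 enrichment is
    lost (direction no longer 'paternal'; a reprogrammed locus may drift
    to 'none' or even a nominally significant maternal deviation)."""
    seen_paternal = False
    for s in stage_order:
        d = chip_directions.get(s)
        if d is None:
            continue
        if d == "paternal":
            seen_paternal = True
        elif seen_paternal:
            return s
    return None


def erv_proximity(
    genes: Sequence, repeats: pd.DataFrame, window: int = 2500
) -> dict[str, tuple[str, ...]]:
    """ERV families with a repeat edge within ``window`` bp of each gene's TSS."""
    out: dict[str, tuple[str, ...]] = {}
    for g in genes:
        fams = []
        for _, rep in repeats[repeats["chrom"] == g.chrom].iterrows():
            # distance from TSS to the nearest repeat edge (0 if the repeat spans it)
            dist = max(rep["start"] - g.tss, g.tss - (rep["end"] - 1), 0)
            if dist <= window:
                fams.append(rep["family"])
        out[g.gene_id] = tuple(sorted(set(fams)))
    return out
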