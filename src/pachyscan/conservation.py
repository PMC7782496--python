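"""Cross-species conservation of piRNA-producing loci.

A mouse cluster's syntenic locus in another species either coincides with a
cluster annotated in that species (same strand: snap to its coordinates) or is
extended by 10 kb on both ends before abundance is measured. A species is
"similar" when the syntenic piRNA output is within 5-fold of the mouse level;
eutherian-conserved requires >= 3 similar species among {human, rhesus,
marmoset, rat, cow}; failing that, a similar rat locus makes the cluster
murine-conserved; otherwise it is mouse-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .expression import pirna_abundance
from .io_formats import GenomicInterval

__all__ = [
    "EUTHERIAN_PANEL",
    "SyntenyRecord",
    "ConservationCall",
    "syntenic_abundance",
    "species_similar",
    "classify_conservation",
]

EUTHERIAN_PANEL = ("human", "rhesus", "marmoset", "rat", "cow")
SIMILAR_MAX_FOLD = 5.0
SYNTENY_EXTEND_BP = 10_000
MIN_SIMILAR_EUTHERIANS = 3


@dataclass
class SyntenyRecord:
    mouse_gene: str
    species: str
    interval: GenomicInterval | None   # None: locus did not lift over


@dataclass
class ConservationCall:
    mouse_gene: str
    conservation_class: str            # eutherian_conserved | murine_conserved | mouse_specific
    similar_species: dict[str, bool]


def syntenic_abundance(
    record: SyntenyRecord,
    species_reads: pd.DataFrame,
    species_unique_total: float,
    species_clusters: list[GenomicInterval] | None = None,
    extend: int = SYNTENY_EXTEND_BP,
) -> tuple[float, str]:
    """piRNA abundance (RPM) of a syntenic locus in another species.

    If the syntenic interval overlaps a same-strand annotated cluster of that
    species, that cluster's own coordinates are used; otherwise the interval is
    extended by ``extend`` bp on both ends. Returns (rpm, provenance) where
    provenance is one of {snapped, extended, unmapped}.
    """
    if record.interval is None:
        return 0.0, "unmapped"
    region = record.interval
    for cl in species_clusters or []:
        if region.overlap(cl) > 0 and cl.strand == region.strand:
            region = cl
            return pirna_abundance(species_reads, region, species_unique_total), "snapped"
    region = GenomicInterval(
        region.chrom, max(0, region.start - extend), region.end + extend, region.strand
    )
    return pirna_abundance(species_reads, region, species_unique_total), "extended"


def species_similar(mouse_rpm: float, species_rpm: float, max_fold: float = SIMILAR_MAX_FOLD) -> bool:
    """Symmetric fold-change < max_fold (strict); zero species output is never similar."""
    if mouse_rpm <= 0:
        raise ValueError("mouse cluster abundance must be positive")
    if species_rpm <= 0:
        return False
    fold = max(species_rpm / mouse_rpm, mouse_rpm / species_rpm)
    return fold < max_fold


def classify_conservation(
    mouse_rpm: float,
    species_rpm: dict[str, float],
    mouse_gene: str = "",
) -> ConservationCall:
    """Conservation class of a mouse cluster from syntenic abundances.

    Only the five eutherian panel species enter the rules; any extra species
    present (opossum, platypus) are carried for reporting but ignored here.
    """
    flags = {
        sp: species_similar(mouse_rpm, species_rpm.get(sp, 0.0))
        for sp in EUTHERIAN_PANEL
    }
    n_similar = sum(flags.values())
    if n_similar >= MIN_SIMILAR_EUTHERIANS:
        cls = "eutherian_conserved"
    elif flags["rat"]:
        cls = "murine_conserved"
    else:
        cls = "mouse_specific"
    return ConservationCall(mouse_gene, cls, flags)


def conservation_table(
    mouse_rpm: pd.Series, species_rpm: pd.DataFrame
) -> pd.DataFrame:
    """Classify every mouse cluster; ``species_rpm`` is gene x species."""
    rows = []
    for gene, rpm in mouse_rpm.items():
        call = classify_conservation(rpm, species_rpm.loc[gene].to_dict(), gene)
        row = {"gene_id": gene, "conservation_class": call.conservation_class}
        row.update({f"similar_{sp}": v for sp, v in call.similar_species.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
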