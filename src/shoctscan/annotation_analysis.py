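"""Downstream censuses over domain annotations.

Four analyses consume the per-protein domain-annotation table: the C-terminal
positional-bias estimator (fraction of proteins whose every target-domain
envelope starts within a fixed window of the C-terminus), the taxonomic
breakdown of distinct species at a chosen clade rank, the domain-architecture
census (N-to-C ordered domain tuples, repeats kept), and the per-protein
copy-number census.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from collections import Counter
from typing import Dict, List, Optional, Sequence as TSequence, Tuple

DEFAULT_WINDOW = 50


@dataclasses.dataclass(frozen=True)
class TerminalBiasResult:
    window: int
    n_proteins: int
    n_within: int
    fraction: float


@dataclasses.dataclass(frozen=True)
class TaxonBreakdown:
    rank: int
    counts: Dict[str, int]  # clade -> distinct species
    percentages: Dict[str, float]  # relative to classified species at the rank
    n_species_classified: int
    n_species_total: int


@dataclasses.dataclass(frozen=True)
class ArchitectureCensus:
    architectures: Dict[Tuple[str, ...], int]
    n_distinct: int


@dataclasses.dataclass(frozen=True)
class CopyNumberCensus:
    copies: Dict[int, int]  # copy count -> number of proteins
    n_regions: int
    n_proteins: int
    max_copies: int


def _by_protein(records: TSequence) -> Dict[str, list]:
    grouped: Dict[str, list] = {}
    for r in records:
        grouped.setdefault(r.protein_id, []).append(r)
    return grouped


def terminal_bias(
    records: TSequence, domain_id: str, window: int = DEFAULT_WINDOW
) -> TerminalBiasResult:
    """Fraction of proteins whose every target-domain envelope lies entirely
    within `window` residues of the C-terminus.

    "Within" means protein_length - env_start + 1 <= window, i.e. the domain's
    first residue falls in the final `window` residues (so the whole envelope
    does). Each protein counts once.
    """
    target = [r for r in records if r.domain_id == domain_id]
    if not target:
        raise ValueError(f"no records for domain {domain_id!r}")
    grouped = _by_protein(target)
    n_within = sum(
        1
        for doms in grouped.values()
        if all(r.protein_length - r.env_start + 1 <= window for r in doms)
    )
    n = len(grouped)
    return TerminalBiasResult(window=window, n_proteins=n, n_within=n_within, fraction=n_within / n)


def taxon_breakdown(
    records: TSequence, taxonomy: Dict[str, str], rank: int = 1
) -> TaxonBreakdown:
    """Distinct-species counts per clade at a path depth (0 = superkingdom,
    1 = phylum, ...). Species identity is the clade path's terminal label;
    percentages are relative to species classified at the requested rank."""
    covered = [r.protein_id for r in records if r.protein_id in taxonomy]
    if not covered:
        raise ValueError("taxonomy covers no annotated protein")
    species_clade: Dict[str, Optional[str]] = {}
    for pid in covered:
        path = [p.strip() for p in taxonomy[pid].split(";")]
        species = path[-1]
        clade = path[rank] if rank < len(path) - 1 else None
        species_clade.setdefault(species, clade)
    counts = Counter(c for c in species_clade.values() if c is not None)
    if not counts:
        raise ValueError(f"rank {rank} absent from all clade paths")
    n_classified = sum(counts.values())
    percentages = {c: 100.0 * n / n_classified for c, n in counts.items()}
    return TaxonBreakdown(
        rank=rank,
        counts=dict(counts),
        percentages=percentages,
        n_species_classified=n_classified,
        n_species_total=len(species_clade),
    )


def architecture_census(
    records: TSequence, domain_id: str
) -> ArchitectureCensus:
    """N-to-C ordered domain-id tuples over proteins containing the target
    domain; repeated domains are kept. Overlapping envelopes on one protein
    order by (env_start, env_end) with a warning."""
    grouped = _by_protein(records)
    archs: Counter = Counter()
    for pid, doms in grouped.items():
        if not any(r.domain_id == domain_id for r in doms):
            continue
        doms = sorted(doms, key=lambda r: (r.env_start, r.env_end))
        for a, b in zip(doms, doms[1:]):
            if b.env_start <= a.env_end:
                warnings.warn(
                    f"overlapping envelopes on {pid}: "
                    f"{a.domain_id}@{a.env_start}-{a.env_end} / "
                    f"{b.domain_id}@{b.env_start}-{b.env_end}"
                )
        archs[tuple(r.domain_id for r in doms)] += 1
    return ArchitectureCensus(architectures=dict(archs), n_distinct=len(archs))


def copy_number_census(records: TSequence, domain_id: str) -> CopyNumberCensus:
    """Per-protein copy counts of the target domain plus region/protein totals."""
    target = [r for r in records if r.domain_id == domain_id]
    if not target:
        raise ValueError(f"no records for domain {domain_id!r}")
    per_protein = Counter(r.protein_id for r in target)
    copies = Counter(per_protein.values())
    n_regions = sum(c * n for c, n in copies.items())
    n_proteins = sum(copies.values())
    return CopyNumberCensus(
        copies=dict(copies),
        n_regions=n_regions,
        n_proteins=n_proteins,
        max_copies=max(copies),
    )


def census_to_json(obj, path) -> None:
    """Serialize any census dataclass to JSON (tuple keys flattened)."""
    d = dataclasses.asdict(obj)
    if "architectures" in d:
        d["architectures"] = {"|".join(k): v for k, v in d["architectures"].items()}
    if "copies" in d:
        d["copies"] = {str(k): v for k, v in d["copies"].items()}
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, sort_keys=True)
        fh.write("\n")
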