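"""Synthetic proteomes with planted short C-terminal two-helix domains.

The generator emulates the search universe for the discovery pipeline: a large
background of i.i.d.-composition proteins, a family of proteins each carrying a
planted ~30-residue two-helix motif (biased to the final 50 residues),
weakened homologs engineered to fall below the 24-bit sequence inclusion
threshold, decoy co-occurring domain families arranged into configurable
architectures, taxonomy labels, and a full ground-truth ledger with a gold
seed alignment. Everything is reproducible byte-for-byte from a single seed.

Motif column model. The planted motif has two invariant positions (a glycine
and a glutamate), two charged-class-preferring and five hydrophobic-class-
preferring positions emitting their class with probability p_cons, and
"framework" positions carrying a modal residue at conservation p_cons + 0.05.
Framework conservation is what makes the family live in the study's bit-score
regime: a ~30-column local model pays roughly 17 bits of structural cost
(entry, exit, flank length model), so crossing the 24-bit inclusion threshold
requires the ~1.5 bits/column of emission information typical of real curated
seed alignments; a motif informative only at its nine annotated positions
would be undetectable at these thresholds by construction. Indels are
forbidden inside both helices and the connecting loop; only the two
N-terminal boundary columns may be deleted, and a single background insertion
may precede the first column.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence as TSequence, Tuple

import numpy as np

from .alphabet import (
    AA_INDEX,
    AMINO_ACIDS,
    BACKGROUND_FREQS,
    CHARGED,
    HYDROPHOBIC,
)
from .seqdata_io import (
    Alignment,
    DomainAnnotationRecord,
    Sequence,
    write_annotations,
    write_fasta,
    write_stockholm,
    write_taxonomy,
)

FAMILY_ID = "SHOCT"
WEAK_ID = "SHOCT_WEAK"

# default column roles for the 30-column motif (1-based)
DEFAULT_HELIX_BLOCKS = ((3, 14), (19, 30))
DEFAULT_LOOP = (15, 18)
DEFAULT_INVARIANT = {8: "G", 24: "E"}
DEFAULT_CHARGED = (5, 21)
DEFAULT_HYDROPHOBIC = (4, 11, 13, 22, 27)


def _class_modal_share(p_cons: float) -> float:
    # within-class share of the modal residue; sharpens to a point mass as
    # p_cons -> 1 so that full conservation yields the consensus string
    return 1.0 - 0.3 * min(1.0, (1.0 - p_cons) / 0.2)


def _invariant_prob(p_cons: float) -> float:
    return min(1.0, p_cons + 0.2)


def _framework_prob(p_cons: float, framework_cons: Optional[float]) -> float:
    return framework_cons if framework_cons is not None else min(1.0, p_cons + 0.05)


@dataclasses.dataclass(frozen=True)
class MotifModel:
    """Per-column emission model of the planted motif family."""

    length: int
    emissions: np.ndarray  # (length, 20), rows sum to 1
    column_kind: Tuple[str, ...]  # 'invariant' | 'charged' | 'hydrophobic' | 'framework'
    modal: Tuple[int, ...]  # modal residue code per column
    helix_blocks: Tuple[Tuple[int, int], ...] = DEFAULT_HELIX_BLOCKS
    loop: Tuple[int, int] = DEFAULT_LOOP
    indel_rate: float = 0.02
    p_cons: float = 0.8
    framework_cons: Optional[float] = None

    def __post_init__(self):
        if not np.allclose(self.emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("motif emission rows must sum to 1")
        lo = [b for b in self.helix_blocks]
        for (s1, e1) in lo:
            if not (1 <= s1 <= e1 <= self.length):
                raise ValueError("helix block outside motif")
        for a, b in zip(lo, lo[1:]):
            if a[1] >= b[0]:
                raise ValueError("helix blocks must be disjoint and ordered")

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[int(np.argmax(row))] for row in self.emissions)

    @property
    def indel_columns(self) -> Tuple[int, ...]:
        """Columns where a deletion is permitted: outside both helices and
        outside the loop (the two N-terminal boundary columns by default)."""
        protected = set()
        for s, e in self.helix_blocks:
            protected.update(range(s, e + 1))
        protected.update(range(self.loop[0], self.loop[1] + 1))
        return tuple(c for c in range(1, self.length + 1) if c not in protected)

    @staticmethod
    def build(
        rng: np.random.Generator,
        length: int = 30,
        p_cons: float = 0.8,
        framework_cons: Optional[float] = None,
        indel_rate: float = 0.02,
        special_positions: bool = True,
        helix_blocks: Tuple[Tuple[int, int], ...] = DEFAULT_HELIX_BLOCKS,
        loop: Tuple[int, int] = DEFAULT_LOOP,
    ) -> "MotifModel":
        """Draw modal residues once (from rng) and assemble column emissions."""
        kinds = ["framework"] * (length + 1)
        modal = [0] * (length + 1)
        if special_positions and length == 30:
            for col, aa in DEFAULT_INVARIANT.items():
                kinds[col] = "invariant"
                modal[col] = AA_INDEX[aa]
            for col in DEFAULT_CHARGED:
                kinds[col] = "charged"
                modal[col] = AA_INDEX[CHARGED[rng.integers(len(CHARGED))]]
            for col in DEFAULT_HYDROPHOBIC:
                kinds[col] = "hydrophobic"
                modal[col] = AA_INDEX[HYDROPHOBIC[rng.integers(len(HYDROPHOBIC))]]
        for col in range(1, length + 1):
            if kinds[col] == "framework":
                modal[col] = int(rng.choice(20, p=BACKGROUND_FREQS))
        emissions = _assemble_emissions(
            length, kinds[1:], modal[1:], p_cons, framework_cons
        )
        return MotifModel(
            length=length,
            emissions=emissions,
            column_kind=tuple(kinds[1:]),
            modal=tuple(modal[1:]),
            helix_blocks=helix_blocks,
            loop=loop,
            indel_rate=indel_rate,
            p_cons=p_cons,
            framework_cons=framework_cons,
        )

    def with_conservation(
        self, p_cons: float, framework_cons: Optional[float] = None, indel_rate: Optional[float] = None
    ) -> "MotifModel":
        """Same modal residues, different conservation level (weak homologs)."""
        emissions = _assemble_emissions(
            self.length, list(self.column_kind), list(self.modal), p_cons, framework_cons
        )
        return dataclasses.replace(
            self,
            emissions=emissions,
            p_cons=p_cons,
            framework_cons=framework_cons,
            indel_rate=self.indel_rate if indel_rate is None else indel_rate,
        )


def _assemble_emissions(length, kinds, modal, p_cons, framework_cons) -> np.ndarray:
    charged_idx = [AA_INDEX[a] for a in CHARGED]
    hydro_idx = [AA_INDEX[a] for a in HYDROPHOBIC]
    share = _class_modal_share(p_cons)
    q_frame = _framework_prob(p_cons, framework_cons)
    q_inv = _invariant_prob(p_cons)
    emissions = np.zeros((length, 20))

    def _spread(row, mass, exclude):
        bg = BACKGROUND_FREQS.copy()
        bg[exclude] = 0.0
        bg /= bg.sum()
        row += mass * bg

    for c in range(length):
        kind, m = kinds[c], modal[c]
        row = emissions[c]
        if kind == "invariant":
            row[m] = q_inv
            _spread(row, 1.0 - q_inv, [m])
        elif kind in ("charged", "hydrophobic"):
            cls = charged_idx if kind == "charged" else hydro_idx
            others = [i for i in cls if i != m]
            row[m] = p_cons * share
            for i in others:
                row[i] += p_cons * (1.0 - share) / len(others)
            _spread(row, 1.0 - p_cons, cls)
        else:
            row[m] = q_frame
            _spread(row, 1.0 - q_frame, [m])
    return emissions


def sample_motif_instance(
    m: MotifModel, rng: np.random.Generator
) -> Tuple[str, List[Tuple[str, int]]]:
    """Sample one motif instance.

    Returns (residues, column map) where the column map holds one
    ('M', col)/('I', 0) entry per emitted residue: 'M' entries name the motif
    column, 'I' entries are boundary insertions before column 1. Deletions are
    possible only at the indel-permitted boundary columns.
    """
    residues: List[str] = []
    colmap: List[Tuple[str, int]] = []
    indel_ok = set(m.indel_columns)
    if m.indel_rate > 0 and rng.random() < m.indel_rate:
        residues.append(AMINO_ACIDS[int(rng.choice(20, p=BACKGROUND_FREQS))])
        colmap.append(("I", 0))
    for col in range(1, m.length + 1):
        if col in indel_ok and m.indel_rate > 0 and rng.random() < m.indel_rate:
            continue  # deletion
        code = int(rng.choice(20, p=m.emissions[col - 1]))
        residues.append(AMINO_ACIDS[code])
        colmap.append(("M", col))
    return "".join(residues), colmap


# ---------------------------------------------------------------------------
# Proteome configuration and generation
# ---------------------------------------------------------------------------

DEFAULT_ARCHITECTURES: Tuple[Tuple[Tuple[str, ...], float], ...] = (
    ((FAMILY_ID,), 0.70),
    (("DOM_A", FAMILY_ID), 0.10),
    (("DOM_B", FAMILY_ID), 0.08),
    (("DOM_A", "DOM_B", FAMILY_ID), 0.06),
    ((FAMILY_ID, FAMILY_ID), 0.06),
)

DEFAULT_TAXONOMY_SCHEME: Tuple[Tuple[str, float], ...] = (
    ("Bacteria;Firmicutes", 0.296),
    ("Bacteria;Proteobacteria", 0.253),
    ("Bacteria;Actinobacteria", 0.191),
    ("Bacteria;Bacteroidetes", 0.052),
    ("Bacteria;Cyanobacteria", 0.041),
    ("Bacteria;OtherPhyla", 0.107),
    ("Archaea;Euryarchaeota", 0.060),
)


@dataclasses.dataclass(frozen=True)
class ProteomeConfig:
    """Study conditions for one synthetic proteome."""

    n_background: int = 10_000
    n_family: int = 60
    n_weak: int = 40
    n_decoy_only: int = 150
    p_c_terminal: float = 0.9
    length_median: float = 300.0
    length_sigma: float = 0.5
    length_min: int = 60
    length_max: int = 2000
    p_cons: float = 0.8
    framework_cons: Optional[float] = None
    indel_rate: float = 0.02
    weak_p_cons: float = 0.35
    decoy_length: int = 40
    decoy_p_cons: float = 0.8
    architectures: Tuple[Tuple[Tuple[str, ...], float], ...] = DEFAULT_ARCHITECTURES
    taxonomy_scheme: Tuple[Tuple[str, float], ...] = DEFAULT_TAXONOMY_SCHEME
    n_species: int = 60

    def __post_init__(self):
        if min(self.n_background, self.n_family, self.n_weak, self.n_decoy_only) < 0:
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.p_c_terminal <= 1.0):
            raise ValueError("p_c_terminal must lie in [0, 1]")
        if self.length_min < 60:
            raise ValueError("proteins shorter than 60 residues are not supported")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground-truth ledger: planted regions, taxonomy, architectures."""

    records: List[DomainAnnotationRecord]
    taxonomy: Dict[str, str]
    architectures: Dict[str, Tuple[str, ...]]
    family_protein_ids: Tuple[str, ...]
    motif: MotifModel
    config: ProteomeConfig
    rng_seed: int


def _draw_length(cfg: ProteomeConfig, rng: np.random.Generator, min_needed: int = 0) -> int:
    L = int(round(float(rng.lognormal(math.log(cfg.length_median), cfg.length_sigma))))
    L = max(cfg.length_min, min(cfg.length_max, L))
    return max(L, min_needed)


def _species_pool(cfg: ProteomeConfig) -> List[str]:
    pool: List[str] = []
    for clade, w in cfg.taxonomy_scheme:
        n = max(1, int(round(w * cfg.n_species)))
        tag = clade.split(";")[-1]
        pool.extend(f"{clade};{tag} sp. {i + 1:03d}" for i in range(n))
    return pool


def generate_proteome(
    config: ProteomeConfig, rng_seed: int
) -> Tuple[List[Sequence], Alignment, SyntheticTruth]:
    """Emit (database, gold seed alignment, truth ledger) for one seed."""
    cfg = config
    rng = np.random.default_rng(rng_seed)

    motif = MotifModel.build(
        rng, p_cons=cfg.p_cons, framework_cons=cfg.framework_cons, indel_rate=cfg.indel_rate
    )
    weak_motif = motif.with_conservation(cfg.weak_p_cons)
    decoys = {
        name: MotifModel.build(
            rng,
            length=cfg.decoy_length,
            p_cons=cfg.decoy_p_cons,
            special_positions=False,
            helix_blocks=((1, cfg.decoy_length),),
            loop=(1, 1),
            indel_rate=0.0,
        )
        for name in sorted({d for arch, _ in cfg.architectures for d in arch if d != FAMILY_ID})
    }

    species = _species_pool(cfg)
    db: List[Sequence] = []
    records: List[DomainAnnotationRecord] = []
    taxonomy: Dict[str, str] = {}
    arch_of: Dict[str, Tuple[str, ...]] = {}
    family_ids: List[str] = []
    seed_rows: List[Tuple[str, List[Tuple[str, int]], str]] = []  # (row id, colmap, residues)

    arch_tuples = [a for a, _ in cfg.architectures]
    arch_weights = np.array([w for _, w in cfg.architectures], dtype=float)
    arch_weights /= arch_weights.sum()

    def _assign_species(pid: str) -> None:
        taxonomy[pid] = species[int(rng.integers(len(species)))]

    def _background_residues(n: int) -> np.ndarray:
        return rng.choice(20, size=n, p=BACKGROUND_FREQS)

    def _build_protein(pid: str, arch: Tuple[str, ...], biased: bool, weak: bool) -> None:
        instances = []
        for dom in arch:
            if dom == FAMILY_ID:
                model = weak_motif if weak else motif
                res, colmap = sample_motif_instance(model, rng)
                instances.append((WEAK_ID if weak else FAMILY_ID, res, colmap))
            else:
                res, colmap = sample_motif_instance(decoys[dom], rng)
                instances.append((dom, res, colmap))
        total = sum(len(r) for _, r, _ in instances)
        min_needed = total + 25 * len(instances) + 80
        L = _draw_length(cfg, rng, min_needed=min_needed)
        seq = _background_residues(L)

        # last family instance (if any) takes the C-terminal placement rule
        last_fam = max(
            (i for i, (d, _, _) in enumerate(instances) if d in (FAMILY_ID, WEAK_ID)),
            default=len(instances) - 1,
        )
        pos = 0
        placements = []
        for i, (dom, res, colmap) in enumerate(instances):
            if i == last_fam:
                continue
            gap = int(rng.integers(5, 21))
            start = pos + gap + 1  # 1-based
            placements.append((i, start))
            pos = start + len(res) - 1
        dom, res, colmap = instances[last_fam]
        upstream_end = pos
        if biased:
            lo, hi = L - 49, L - len(res) + 1
        else:
            lo, hi = upstream_end + 6, L - 50
        start_last = int(rng.integers(lo, hi + 1))
        placements.append((last_fam, start_last))

        for i, start in placements:
            dom, res, colmap = instances[i]
            codes = np.array([AA_INDEX[c] for c in res])
            seq[start - 1 : start - 1 + len(res)] = codes
            end = start + len(res) - 1
            records.append(
                DomainAnnotationRecord(pid, L, dom, start, end, 0.0)
            )
            if dom == FAMILY_ID:
                seed_rows.append((f"{pid}/{start}-{end}", colmap, res))
        residues = "".join(AMINO_ACIDS[c] for c in seq)
        db.append(Sequence(id=pid, residues=residues))
        arch_of[pid] = arch
        _assign_species(pid)

    for i in range(cfg.n_family):
        pid = f"FAM{i + 1:05d}"
        arch = arch_tuples[int(rng.choice(len(arch_tuples), p=arch_weights))]
        biased = bool(rng.random() < cfg.p_c_terminal)
        _build_protein(pid, arch, biased, weak=False)
        family_ids.append(pid)

    for i in range(cfg.n_weak):
        pid = f"WEAK{i + 1:04d}"
        biased = bool(rng.random() < cfg.p_c_terminal)
        _build_protein(pid, (FAMILY_ID,), biased, weak=True)

    decoy_archs = [(d,) for d in sorted(decoys)]
    for i in range(cfg.n_decoy_only):
        pid = f"DEC{i + 1:05d}"
        arch = decoy_archs[int(rng.integers(len(decoy_archs)))] if decoy_archs else ()
        if arch:
            _build_protein(pid, arch, biased=False, weak=False)
        else:
            L = _draw_length(cfg, rng)
            db.append(Sequence(pid, "".join(AMINO_ACIDS[c] for c in _background_residues(L))))
            arch_of[pid] = ()
            _assign_species(pid)

    for i in range(cfg.n_background):
        pid = f"BG{i + 1:06d}"
        L = _draw_length(cfg, rng)
        db.append(Sequence(pid, "".join(AMINO_ACIDS[c] for c in _background_residues(L))))
        arch_of[pid] = ()
        _assign_species(pid)

    seed_alignment = _gold_alignment(seed_rows, motif.length) if seed_rows else None
    truth = SyntheticTruth(
        records=records,
        taxonomy=taxonomy,
        architectures=arch_of,
        family_protein_ids=tuple(family_ids),
        motif=motif,
        config=cfg,
        rng_seed=rng_seed,
    )
    return db, seed_alignment, truth


def _gold_alignment(seed_rows, length: int) -> Alignment:
    n_ins = max(sum(1 for s, _ in cm if s == "I") for _, cm, _ in seed_rows)
    rows = []
    for rid, colmap, res in seed_rows:
        by_col = {}
        ins = []
        for (state, col), aa in zip(colmap, res):
            if state == "M":
                by_col[col] = aa
            else:
                ins.append(aa)
        chars = ["."] * n_ins
        for j, aa in enumerate(ins):
            chars[n_ins - len(ins) + j] = aa
        chars += [by_col.get(c, "-") for c in range(1, length + 1)]
        rows.append((rid, "".join(chars)))
    return Alignment.from_rows(rows)


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RecoveryReport:
    sensitivity: float
    precision: Optional[float]
    n_planted: int
    n_recovered: int
    n_hit_domains: int
    n_true_domains: int
    protein_sensitivity: float


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def evaluate_recovery(
    hits: TSequence,
    truth: SyntheticTruth,
    overlap_rule: float = 0.5,
    target_family: str = FAMILY_ID,
    precision_families: Tuple[str, ...] = (FAMILY_ID, WEAK_ID),
) -> RecoveryReport:
    """Region-level sensitivity/precision of search hits against planted truth.

    A planted region is recovered if some reported envelope on the same protein
    overlaps it by >= overlap_rule of the planted length; a reported envelope
    is true if it overlaps any planted region of the precision families by the
    same rule. Precision is None when there are no reported envelopes.
    """
    known = {r.protein_id for r in truth.records} | set(truth.taxonomy)
    for h in hits:
        if h.seq_id not in known:
            raise ValueError(f"hit id {h.seq_id!r} not in the truth universe")
    planted = [r for r in truth.records if r.domain_id == target_family]
    hit_doms: Dict[str, list] = {}
    for h in hits:
        hit_doms.setdefault(h.seq_id, []).extend(h.domains)

    n_rec = 0
    for r in planted:
        need = overlap_rule * (r.env_end - r.env_start + 1)
        if any(
            _overlap(r.env_start, r.env_end, d.env_start, d.env_end) >= need
            for d in hit_doms.get(r.protein_id, [])
        ):
            n_rec += 1

    truth_by_protein: Dict[str, list] = {}
    for r in truth.records:
        if r.domain_id in precision_families:
            truth_by_protein.setdefault(r.protein_id, []).append(r)
    n_dom = 0
    n_true = 0
    for pid, doms in hit_doms.items():
        for d in doms:
            n_dom += 1
            for r in truth_by_protein.get(pid, []):
                need = overlap_rule * (r.env_end - r.env_start + 1)
                if _overlap(r.env_start, r.env_end, d.env_start, d.env_end) >= need:
                    n_true += 1
                    break

    planted_proteins = {r.protein_id for r in planted}
    hit_proteins = {h.seq_id for h in hits}
    prot_sens = (
        len(planted_proteins & hit_proteins) / len(planted_proteins)
        if planted_proteins
        else float("nan")
    )
    return RecoveryReport(
        sensitivity=n_rec / len(planted) if planted else float("nan"),
        precision=(n_true / n_dom) if n_dom else None,
        n_planted=len(planted),
        n_recovered=n_rec,
        n_hit_domains=n_dom,
        n_true_domains=n_true,
        protein_sensitivity=prot_sens,
    )


# ---------------------------------------------------------------------------
# On-disk emission
# ---------------------------------------------------------------------------

def write_proteome(db, seed_alignment, truth, outdir) -> None:
    """Emit FASTA + Stockholm + truth TSV + taxonomy TSV + config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(db, outdir / "database.fasta")
    if seed_alignment is not None:
        write_stockholm(seed_alignment, outdir / "gold_seed.sto")
    write_annotations(truth.records, outdir / "truth_annotations.tsv")
    write_taxonomy(truth.taxonomy, outdir / "taxonomy.tsv")
    cfg = dataclasses.asdict(truth.config)
    cfg["rng_seed"] = truth.rng_seed
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
        fh.write("\n")
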