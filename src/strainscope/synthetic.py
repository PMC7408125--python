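"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structure of a strain-resolved natural-product
study: a library of related compounds split into three groups that share
diagnostic tag fragments and family fragmentation patterns; heterogeneous,
partly strain-exclusive production with log-normally distributed abundances
over exact structural zeros; replicate MS/MS spectra per produced
(strain, compound) pair; Gaussian EIC peaks whose areas encode the true
abundances; core/accessory/unique BGC presence structure; and coding
sequences with planted silent/non-silent substitutions and in-frame
deletions classified under the bacterial codon table at planting time.

Every generator is a pure function of its inputs and the seed, so the
downstream recovery tests can compare against exact truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .compounds import CompoundRecord
from .formula import PROTON_MASS, Formula, IonReading, ion_mz
from .genomecmp import CODON_TABLE_ID, MutationEvent
from .quantify import StrainCompoundMatrix
from .spectra import EICTrace, Spectrum
from .tags import TagDefinition, default_tag_set

__all__ = ["SimulationConfig", "SynthCompound", "SyntheticLibrary", "MutationPlan",
           "make_library", "make_production", "simulate_spectra", "simulate_eic",
           "make_bgc_matrix", "random_reference_cds", "make_cds_set"]

_PROTONATED = IonReading("protonated-neutral")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the metabolomics-side generators.

    Defaults mirror the study design the pipeline targets: seven strains
    profiled by MS/MS with the first as reference, 24 compounds split
    across the three diagnostic groups (eight per group in expectation,
    the observed group sizes; pass ``compounds_per_group`` for exact
    counts), a modest strain-exclusive
    production probability, wide log-normal abundance spread over exact
    structural zeros, and four replicate scans per produced pair so that
    consensus clustering at minimum cluster size four retains every
    compound.
    """

    n_strains: int = 7
    compounds_per_group: Mapping[str, int] | None = None   # default {"1": 8, "2": 8, "3": 8}
    n_compounds: int = 24            # used with group_probs when counts not given
    group_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    specificity: float = 0.15        # P(compound produced by exactly one strain)
    presence_prob: float = 0.55      # per-strain presence otherwise
    abundance_mu: float = 10.0       # log-normal parameters (natural log)
    abundance_sigma: float = 1.0
    replicates: int = 4              # MS/MS scans per produced pair
    noise_peaks: int = 5
    noise_intensity: float = 0.05    # ceiling, fraction of base peak
    mz_jitter: float = 0.002         # Da, 1 sigma
    nl_rate: float = 0.0             # P(tag appears only as neutral loss), NL-capable groups
    min_precursor_spacing: float = 0.5   # Da between compound ions (0 disables)
    rt_start: float = 60.0
    rt_end: float = 540.0
    rt_step: float = 0.5             # seconds
    peak_sigma: float = 3.0          # chromatographic sigma, seconds
    eic_noise: float = 0.0           # additive baseline noise sd (intensity units)
    seed: int = 0

    def group_counts(self) -> dict[str, int]:
        if self.compounds_per_group is not None:
            return dict(self.compounds_per_group)
        return {"1": 0, "2": 0, "3": 0}

    def strains(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_strains)]

    def rt_grid(self) -> np.ndarray:
        n = int(round((self.rt_end - self.rt_start) / self.rt_step)) + 1
        return self.rt_start + self.rt_step * np.arange(n)


@dataclass(frozen=True)
class SynthCompound:
    """One synthetic compound and its spectral/chromatographic truth."""

    name: str
    formula: Formula
    ion_mz: float
    group: str
    tag_mz: float
    use_neutral_loss: bool
    fragments: tuple[tuple[float, float], ...]   # (m/z, relative intensity)
    rt: float

    def to_record(self, producers: frozenset[str] = frozenset()) -> CompoundRecord:
        return CompoundRecord(
            name=self.name, formula=self.formula, reading=_PROTONATED,
            mz=self.ion_mz, dm_ppm=0.0, group=self.group,
            neutral_loss=self.use_neutral_loss, alt_tag=False,
            producing_strains=producers, best_producers=(), known=False,
        )


@dataclass
class SyntheticLibrary:
    compounds: list[SynthCompound]
    tag_set: list[TagDefinition]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compounds]

    def records(self, production: StrainCompoundMatrix | None = None) -> list[CompoundRecord]:
        out = []
        for c in self.compounds:
            producers = frozenset()
            if production is not None and c.name in production.values.columns:
                col = production.values[c.name]
                producers = frozenset(col.index[col > 0])
            out.append(c.to_record(producers))
        return out


def _sample_formula(group: str, rng: np.random.Generator) -> Formula:
    """Random CHNOS composition plausible for the group (group 2 carries sulfur)."""
    nC = int(rng.integers(14, 31))
    nS = int(rng.integers(1, 3)) if group == "2" else 0
    nN = {"1": int(rng.integers(0, 2)), "2": int(rng.integers(2, 4)),
          "3": 1}[group]
    nO = int(rng.integers(3, 9))
    max_h = 2 * nC + 2 + nN
    r = int(rng.integers(4, 13))             # rings + double bonds
    nH = max_h - 2 * r
    nH = int(min(max(nH, 4), max_h))
    if (nH + nN) % 2:                        # keep H count parity sane for even-electron ions
        nH = max(nH - 1, 3)
    return Formula({"C": nC, "H": nH, "N": nN, "O": nO, "S": nS})


def make_library(cfg: SimulationConfig) -> SyntheticLibrary:
    """Generate a compound library with group structure and shared fragments.

    Compounds of one group share a fragment pool: four dominant "core"
    fragments every member carries (the common scaffold) plus minor
    fragments each member samples individually, and the group's diagnostic
    tag.  Precursor ions are kept at least 0.5 Da apart so consensus
    clustering can separate compounds.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    tag_set = default_tag_set()
    tags = {t.group: t for t in tag_set}
    counts = cfg.group_counts()
    if cfg.compounds_per_group is None:
        draws = rng.choice(["1", "2", "3"], size=cfg.n_compounds, p=cfg.group_probs)
        for g in draws:
            counts[g] += 1

    # Per-group fragment pools in disjoint m/z windows, below every precursor.
    pools: dict[str, list[tuple[float, float]]] = {}
    windows = {"1": (130.0, 165.0), "2": (190.0, 225.0), "3": (230.0, 262.0)}
    for g, (lo, hi) in windows.items():
        mzs = np.sort(rng.uniform(lo, hi, size=10))
        core = [(float(m), float(rng.uniform(0.5, 1.0))) for m in mzs[:4]]
        minor = [(float(m), float(rng.uniform(0.05, 0.2))) for m in mzs[4:]]
        pools[g] = core + minor

    compounds: list[SynthCompound] = []
    taken_mz: list[float] = []
    idx = 0
    for g in ("1", "2", "3"):
        for _ in range(counts.get(g, 0)):
            idx += 1
            for _attempt in range(200):
                f = _sample_formula(g, rng)
                mz = ion_mz(f, _PROTONATED)
                spacing = cfg.min_precursor_spacing
                if mz > 280 and (spacing <= 0 or all(abs(mz - t) > spacing for t in taken_mz)):
                    break
            else:
                raise RuntimeError("could not place a well-separated precursor")
            taken_mz.append(mz)
            pool = pools[g]
            n_minor = int(rng.integers(0, 7))
            minor_idx = rng.choice(6, size=n_minor, replace=False) if n_minor else []
            fragments = list(pool[:4]) + [pool[4 + int(i)] for i in minor_idx]
            fragments = [(m, i * float(rng.uniform(0.9, 1.1))) for m, i in fragments]
            tag = tags[g]
            use_nl = bool(tag.allow_neutral_loss and rng.random() < cfg.nl_rate)
            compounds.append(SynthCompound(
                name=f"SYN{idx:03d}",
                formula=f,
                ion_mz=mz,
                group=g,
                tag_mz=tag.tag_mz,
                use_neutral_loss=use_nl,
                fragments=tuple(sorted(fragments)),
                rt=float(rng.uniform(cfg.rt_start + 30, cfg.rt_end - 30)),
            ))
    return SyntheticLibrary(compounds=compounds, tag_set=tag_set)


def make_production(
    library: SyntheticLibrary,
    strains: Sequence[str] | None = None,
    cfg: SimulationConfig = SimulationConfig(),
) -> StrainCompoundMatrix:
    """Strain × compound abundances: log-normal where produced, exact 0 where not.

    With probability ``specificity`` a compound is produced by exactly one
    strain; otherwise each strain produces it independently with
    ``presence_prob`` (at least one producer is enforced).  The first
    strain is the reference.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    strains = list(strains) if strains is not None else cfg.strains()
    if not strains:
        raise ValueError("need at least one strain")
    values = pd.DataFrame(0.0, index=strains, columns=library.names)
    for c in library.names:
        if rng.random() < cfg.specificity:
            producers = [strains[int(rng.integers(len(strains)))]]
        else:
            mask = rng.random(len(strains)) < cfg.presence_prob
            if not mask.any():
                mask[int(rng.integers(len(strains)))] = True
            producers = [s for s, m in zip(strains, mask) if m]
        for s in producers:
            values.loc[s, c] = float(rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma))
    return StrainCompoundMatrix(values=values, reference_strain=strains[0])


def simulate_spectra(
    library: SyntheticLibrary,
    production: StrainCompoundMatrix,
    cfg: SimulationConfig = SimulationConfig(),
) -> list[Spectrum]:
    """Replicate MS/MS scans for every produced (strain, compound) pair.

    Each scan carries the compound's family fragments, its diagnostic tag
    (or the neutral-loss twin at precursor minus the tag's neutral mass),
    and uniform noise peaks capped at ``noise_intensity`` of the base peak;
    all m/z values receive Gaussian jitter.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    by_name = {c.name: c for c in library.compounds}
    spectra: list[Spectrum] = []
    for s in production.strains:
        for name in production.compounds:
            abundance = float(production.values.loc[s, name])
            if abundance <= 0:
                continue
            comp = by_name[name]
            for rep in range(cfg.replicates):
                mzs: list[float] = []
                ints: list[float] = []
                for fmz, rel in comp.fragments:
                    mzs.append(fmz)
                    ints.append(rel * abundance)
                if comp.use_neutral_loss:
                    mzs.append(comp.ion_mz - (comp.tag_mz - PROTON_MASS))
                else:
                    mzs.append(comp.tag_mz)
                ints.append(0.7 * abundance)
                base = max(ints)
                for _ in range(cfg.noise_peaks):
                    mzs.append(float(rng.uniform(50.0, comp.ion_mz - 5.0)))
                    ints.append(float(rng.uniform(0.0, cfg.noise_intensity * base)))
                mz_arr = np.array(mzs) + rng.normal(0.0, cfg.mz_jitter, size=len(mzs))
                spectra.append(Spectrum(
                    id=f"{s}:{name}:r{rep + 1}",
                    precursor_mz=float(comp.ion_mz + rng.normal(0.0, cfg.mz_jitter)),
                    mz=mz_arr,
                    intensity=np.array(ints),
                    charge=1,
                    rt=float(max(comp.rt + rng.normal(0.0, 1.0), 0.0)),
                    strain=s,
                ))
    return spectra


def simulate_eic(
    library: SyntheticLibrary,
    production: StrainCompoundMatrix,
    cfg: SimulationConfig = SimulationConfig(),
) -> dict[str, list[EICTrace]]:
    """Per-strain EIC channels: Gaussian peaks with area equal to true abundance."""
    rng = np.random.default_rng([cfg.seed, 4])
    grid = cfg.rt_grid()
    out: dict[str, list[EICTrace]] = {}
    for s in production.strains:
        traces = []
        for comp in library.compounds:
            abundance = float(production.values.loc[s, comp.name])
            y = np.zeros_like(grid)
            if abundance > 0:
                amp = abundance / (cfg.peak_sigma * math.sqrt(2 * math.pi))
                y = amp * np.exp(-0.5 * ((grid - comp.rt) / cfg.peak_sigma) ** 2)
            if cfg.eic_noise > 0:
                y = np.clip(y + rng.normal(0.0, cfg.eic_noise, size=grid.size), 0.0, None)
            traces.append(EICTrace(rt=grid.copy(), intensity=y,
                                   target_mz=comp.ion_mz, tol_da=0.01))
        out[s] = traces
    return out


def make_bgc_matrix(
    n_strains: int = 18,
    n_core: int = 18,
    accessory: int | Sequence[Sequence[int]] = 22,
    unique: int | Sequence[int] = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary strains × BGC-family matrix with core/accessory/unique structure.

    ``accessory`` is either a count (members drawn with random prevalence
    between 2 and n_strains − 1) or explicit strain-index sets; ``unique``
    is a count (random carrier) or explicit carrier indices.  Defaults
    mirror an 18-strain collection with an 18-family core, 22 accessory and
    2 single-strain families (42 in total).
    """
    rng = np.random.default_rng([seed, 5])
    strains = [f"S{i + 1:02d}" for i in range(n_strains)]
    cols: dict[str, np.ndarray] = {}
    fam = 0
    for _ in range(n_core):
        fam += 1
        cols[f"BGC{fam:03d}"] = np.ones(n_strains, dtype=int)
    acc_sets: list[Sequence[int]]
    if isinstance(accessory, int):
        acc_sets = []
        for _ in range(accessory):
            prevalence = int(rng.integers(2, max(n_strains, 3)))
            acc_sets.append(sorted(rng.choice(n_strains, size=min(prevalence, n_strains - 1),
                                              replace=False).tolist()))
    else:
        acc_sets = [sorted(s) for s in accessory]
    for members in acc_sets:
        fam += 1
        col = np.zeros(n_strains, dtype=int)
        col[list(members)] = 1
        cols[f"BGC{fam:03d}"] = col
    uniq: list[int]
    if isinstance(unique, int):
        uniq = [int(rng.integers(n_strains)) for _ in range(unique)]
    else:
        uniq = list(unique)
    for carrier in uniq:
        fam += 1
        col = np.zeros(n_strains, dtype=int)
        col[carrier] = 1
        cols[f"BGC{fam:03d}"] = col
    return pd.DataFrame(cols, index=strains)


# --- CDS mutation planting ---------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


def _translate(codon: str) -> str:
    return str(Seq(codon).translate(table=CODON_TABLE_ID))


@dataclass(frozen=True)
class MutationPlan:
    """Planted mutation load for one strain."""

    n_silent: int = 0
    n_non_silent: int = 0
    n_deletions: int = 0


def random_reference_cds(n_genes: int = 16, n_codons: int = 200, seed: int = 0) -> dict[str, str]:
    """Random reference ORFs: ATG start, stop-free body, TAA stop."""
    rng = np.random.default_rng([seed, 6])
    genes = {}
    for i in range(n_genes):
        codons = ["ATG"]
        while len(codons) < n_codons - 1:
            c = "".join(rng.choice(list(_BASES), size=3))
            if c not in _STOPS:
                codons.append(c)
        codons.append("TAA")
        genes[f"g{i + 1:02d}"] = "".join(codons)
    return genes


def _single_nt_variants(codon: str):
    for pos in range(3):
        for b in _BASES:
            if b != codon[pos]:
                yield codon[:pos] + b + codon[pos + 1:]


def make_cds_set(
    reference: Mapping[str, str],
    plans: Mapping[str, MutationPlan],
    seed: int = 0,
) -> tuple[dict[str, dict[str, str]], list[MutationEvent]]:
    """Plant substitutions and in-frame deletions into per-strain CDS copies.

    Substitutions are single-nucleotide and classified at planting time by
    translating the reference and mutated codon under the bacterial code;
    deletions remove one whole codon chosen to differ from both neighbours
    (keeping the alignment unambiguous).  Returns the mutated gene sets and
    the exact truth events.
    """
    rng = np.random.default_rng([seed, 7])
    for gene, seq in reference.items():
        if len(seq) % 3:
            raise ValueError(f"reference gene {gene!r} length not divisible by 3")
    genes = sorted(reference)
    strains_out: dict[str, dict[str, str]] = {}
    events: list[MutationEvent] = []
    for strain in sorted(plans):
        plan = plans[strain]
        mutated = {g: list(reference[g]) for g in genes}
        used: set[tuple[str, int]] = set()   # (gene, codon index) already touched

        def pick_codon(gene: str, n_codons: int) -> int:
            for _ in range(200):
                ci = int(rng.integers(1, n_codons - 1))   # skip start and stop
                if (gene, ci) not in used:
                    return ci
            raise RuntimeError("could not find a free codon to mutate")

        for kind, n in (("silent", plan.n_silent), ("non-silent", plan.n_non_silent)):
            for _ in range(n):
                for _attempt in range(200):
                    gene = genes[int(rng.integers(len(genes)))]
                    n_codons = len(reference[gene]) // 3
                    ci = pick_codon(gene, n_codons)
                    ref_codon = reference[gene][3 * ci:3 * ci + 3]
                    ref_aa = _translate(ref_codon)
                    options = [
                        v for v in _single_nt_variants(ref_codon)
                        if v not in _STOPS
                        and ((_translate(v) == ref_aa) if kind == "silent"
                             else (_translate(v) != ref_aa))
                    ]
                    if options:
                        break
                else:
                    raise RuntimeError(f"could not plant a {kind} substitution")
                alt_codon = options[int(rng.integers(len(options)))]
                used.add((gene, ci))
                mutated[gene][3 * ci:3 * ci + 3] = list(alt_codon)
                first_diff = next(k for k in range(3) if ref_codon[k] != alt_codon[k])
                events.append(MutationEvent(
                    strain=strain, gene=gene, codon=ci + 1,
                    nt_pos=3 * ci + first_diff + 1, kind=kind,
                    ref=ref_aa, alt=_translate(alt_codon),
                ))
        deletions: dict[str, list[int]] = {}
        for _ in range(plan.n_deletions):
            for _attempt in range(500):
                gene = genes[int(rng.integers(len(genes)))]
                seq = reference[gene]
                n_codons = len(seq) // 3
                ci = pick_codon(gene, n_codons)
                s3 = 3 * ci
                codon = seq[s3:s3 + 3]
                # a deletion gap can slide left iff seq[s-1] == seq[s+2] and
                # right iff seq[s] == seq[s+3]; blocking both keeps the
                # optimal alignment unique and codon-aligned
                if seq[s3 - 1] != seq[s3 + 2] and seq[s3] != seq[s3 + 3]:
                    break
            else:
                raise RuntimeError("could not place an unambiguous deletion")
            used.add((gene, ci))
            deletions.setdefault(gene, []).append(ci)
            events.append(MutationEvent(
                strain=strain, gene=gene, codon=ci + 1, nt_pos=3 * ci + 1,
                kind="in-frame deletion", ref=codon, alt="-", length=3,
            ))
        # apply deletions last, right-to-left, so earlier indices stay valid
        for gene, codon_indices in deletions.items():
            for ci in sorted(codon_indices, reverse=True):
                mutated[gene][3 * ci:3 * ci + 3] = []
        strains_out[strain] = {g: "".join(chars) for g, chars in mutated.items()}
    events.sort(key=lambda e: (e.strain, e.gene, e.nt_pos))
    return strains_out, events
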