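"""Synthetic clone-level bisulfite datasets with known ground truth.

Real inputs to this pipeline are Sanger-sequenced plasmid clones, each
representing one DNA molecule from one cell of a sorted population
(~20 clones per donor x population x region x strand).  This module
generates datasets with that structure: per-CpG, per-strand methylation
probabilities, incomplete bisulfite conversion, uniform sequencing
error, and (optionally) X-inactivation mosaicism — a clone-level mixture
of an active-X and an inactive-X profile, as arises at X-linked loci
such as FOXP3 in female donors.

Every dataset is reproducible bit-exactly from (config, seed): one
master seed is combined with a stable hash of each
(donor, population, region, strand) group key to derive per-group
generators, so adding or reordering groups does not perturb the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon import (
    BOTTOM,
    TOP,
    Amplicon,
    ConversionModel,
    in_silico_convert,
    write_reference_fasta,
)

__all__ = [
    "MethylationProfile",
    "XiMosaic",
    "DonorConfig",
    "SimulationTruth",
    "SimulatedDataset",
    "simulate_clone",
    "simulate_dataset",
    "simulate_group_percents",
    "make_scenario",
    "make_study",
    "scenario_amplicons",
    "synthetic_reference",
    "SCENARIOS",
    "POPULATIONS",
    "TREG_POPULATIONS",
    "REGION_CPG_COUNTS",
    "X_LINKED_REGIONS",
]

#: The five sorted cell populations compared by the assay.
POPULATIONS = ("CD34", "CD45RA+CD15s-", "CD45RA-CD15s-", "CD45RA-CD15s+", "Tcon")
#: The three regulatory-T-cell subsets (naive, non-suppressive, effector).
TREG_POPULATIONS = ("CD45RA+CD15s-", "CD45RA-CD15s-", "CD45RA-CD15s+")

#: CpG counts of the six assayed gene regions.
REGION_CPG_COUNTS = {
    "CAMTA1_intron": 13,
    "FUT7_promoter": 19,
    "FOXP3_enhancer": 42,
    "FOXP3_preTSDR": 10,
    "FOXP3_promoter": 10,
    "FOXP3_TSDR": 15,
}
#: Regions on the X chromosome, subject to Xi mosaicism in female donors.
X_LINKED_REGIONS = frozenset(
    {"FOXP3_enhancer", "FOXP3_preTSDR", "FOXP3_promoter", "FOXP3_TSDR"}
)

INDEPENDENT = "independent"
CLONE_LEVEL = "clone_level"


@dataclass(frozen=True)
class MethylationProfile:
    """Generating per-CpG methylation probabilities for one group.

    ``correlation_mode="independent"`` draws each CpG of a clone as an
    independent Bernoulli(p_meth[i]); ``"clone_level"`` draws one latent
    epiallele per clone — all-methylated with probability mean(p_meth),
    else all-unmethylated — reproducing the bimodal rows seen in
    clone-level lollipop data.
    """

    region: str
    strand: str
    p_meth: tuple[float, ...]
    correlation_mode: str = INDEPENDENT

    def __post_init__(self) -> None:
        p = tuple(float(x) for x in self.p_meth)
        if any(not 0.0 <= x <= 1.0 for x in p):
            raise ValueError("p_meth entries must be in [0, 1]")
        if self.correlation_mode not in (INDEPENDENT, CLONE_LEVEL):
            raise ValueError(f"unknown correlation_mode {self.correlation_mode!r}")
        object.__setattr__(self, "p_meth", p)

    @property
    def n_cpg(self) -> int:
        return len(self.p_meth)


@dataclass(frozen=True)
class XiMosaic:
    """Clone-level mixture modelling X-inactivation in female donors.

    A fraction ``fraction_inactive`` of clones is drawn from the
    region/strand-matched inactive-X profile instead of the group's
    active profile.  Applied only to X-linked regions of female donors.
    """

    fraction_inactive: float
    inactive_profiles: Mapping[tuple[str, str], MethylationProfile]

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_inactive <= 1.0:
            raise ValueError("fraction_inactive must be in [0, 1]")


@dataclass(frozen=True)
class DonorConfig:
    """One donor's generating configuration.

    ``profiles`` maps (population, region, strand) to the group's
    :class:`MethylationProfile`.  Defaults follow the assay design:
    20 clones per group, Sanger-like substitution error 1e-3, kit-spec
    conversion/protection rates 0.995.
    """

    donor_id: str
    sex: str
    populations: tuple[str, ...]
    profiles: Mapping[tuple[str, str, str], MethylationProfile]
    xi_mosaic: XiMosaic | None = None
    clones_per_group: int = 20
    seq_error_rate: float = 0.001
    conversion: ConversionModel = field(default_factory=ConversionModel)
    x_linked_regions: frozenset[str] = X_LINKED_REGIONS

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.clones_per_group < 1:
            raise ValueError("clones_per_group must be >= 1")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise ValueError("seq_error_rate must be in [0, 1)")

    def group_keys(self):
        """(population, region, strand) keys in deterministic order."""
        prs = sorted({(r, s) for (_, r, s) in self.profiles})
        for pop in self.populations:
            for region, strand in prs:
                if (pop, region, strand) in self.profiles:
                    yield pop, region, strand

    def mosaic_for(self, population: str, region: str, strand: str) -> XiMosaic | None:
        if (
            self.xi_mosaic is not None
            and self.sex == "F"
            and region in self.x_linked_regions
            and (region, strand) in self.xi_mosaic.inactive_profiles
        ):
            return self.xi_mosaic
        return None


@dataclass
class SimulationTruth:
    """Realized ground truth behind a synthetic dataset.

    ``states`` maps (donor, population, region, strand) to the realized
    clones x CpG boolean state matrix; ``inactive_x`` flags which clones
    were drawn from the inactive-X profile (all False without mosaicism).
    """

    states: dict[tuple[str, str, str, str], np.ndarray]
    inactive_x: dict[tuple[str, str, str, str], np.ndarray]
    configs: tuple[DonorConfig, ...]
    seed: int

    def percent(self, key: tuple[str, str, str, str]) -> np.ndarray:
        """Realized per-CpG percent methylation of one group."""
        return self.states[key].mean(axis=0) * 100.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (donor, pop, region, strand), mat in self.states.items():
            for i, clone_states in enumerate(mat):
                rows.append(
                    {
                        "clone_id": _clone_id(donor, pop, region, strand, i),
                        "donor": donor,
                        "population": pop,
                        "region": region,
                        "strand": strand,
                        **{f"CpG_{j + 1}": int(v) for j, v in enumerate(clone_states)},
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class SimulatedDataset:
    """Clone sequences + sample sheet + ground truth for one simulation."""

    clones: list[tuple[str, str]]  # (clone_id, sequence)
    sample_sheet: pd.DataFrame
    truth: SimulationTruth
    amplicons: dict[tuple[str, str], Amplicon]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write clone FASTA, sample-sheet/truth TSVs and reference FASTA."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "clones_fasta": outdir / "clones.fasta",
            "sample_sheet": outdir / "sample_sheet.tsv",
            "truth": outdir / "truth.tsv",
            "reference_fasta": outdir / "reference.fasta",
        }
        with open(paths["clones_fasta"], "w") as fh:
            for clone_id, seq in self.clones:
                fh.write(f">{clone_id}\n{seq}\n")
        self.sample_sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
        self.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
        write_reference_fasta(self.amplicons.values(), paths["reference_fasta"])
        return paths


def _group_rng(seed: int, key: tuple[str, ...]) -> np.random.Generator:
    """Per-group generator from the master seed and a stable key hash."""
    digest = hashlib.sha256("|".join(key).encode()).digest()
    child = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), child]))


def _clone_id(donor: str, pop: str, region: str, strand: str, i: int) -> str:
    pop_safe = pop.replace("+", "p").replace("-", "n")
    return f"{donor}.{pop_safe}.{region}.{strand}.c{i + 1:03d}"


def _draw_states(
    profile: MethylationProfile, rng: np.random.Generator
) -> np.ndarray:
    p = np.asarray(profile.p_meth)
    if profile.correlation_mode == CLONE_LEVEL:
        return np.full(p.size, rng.random() < p.mean())
    return rng.random(p.size) < p


_OTHER_BASES = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        base = out[i]
        if base in _OTHER_BASES:
            out[i] = _OTHER_BASES[base][rng.integers(3)]
    return "".join(out)


def simulate_clone(
    profile: MethylationProfile,
    amplicon: Amplicon,
    model: ConversionModel,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, str]:
    """Simulate one sequenced clone.

    Draws the clone's per-CpG methylation states from ``profile``,
    bisulfite-converts the amplicon under ``model``, then applies
    uniform substitution errors.  Returns ``(true_states, sequence)``.
    """
    if profile.n_cpg != amplicon.n_cpg:
        raise ValueError(
            f"profile has {profile.n_cpg} CpGs, amplicon {amplicon.name} has {amplicon.n_cpg}"
        )
    states = _draw_states(profile, rng)
    seq = in_silico_convert(amplicon, states, model, rng)
    return states, _apply_errors(seq, error_rate, rng)


def simulate_group_percents(
    profile: MethylationProfile,
    n_clones: int,
    rng: np.random.Generator,
    mosaic: XiMosaic | None = None,
) -> np.ndarray:
    """Per-CpG percent methylation for one simulated group, states only.

    Matrix-level shortcut used by large replicate studies (test
    calibration, power): draws the same clone states the full pipeline
    would generate, but skips the sequence round trip, which is the
    identity under perfect conversion and error-free calling.
    """
    p = np.asarray(profile.p_meth)
    if mosaic is not None:
        inactive = mosaic.inactive_profiles[(profile.region, profile.strand)]
        q = np.asarray(inactive.p_meth)
        choose_inactive = rng.random(n_clones) < mosaic.fraction_inactive
        mat = np.where(
            choose_inactive[:, None], rng.random((n_clones, p.size)) < q, rng.random((n_clones, p.size)) < p
        )
        return mat.mean(axis=0) * 100.0
    if profile.correlation_mode == CLONE_LEVEL:
        alleles = rng.random(n_clones) < p.mean()
        return np.full(p.size, alleles.mean() * 100.0)
    counts = rng.binomial(n_clones, p)
    return counts / n_clones * 100.0


def simulate_dataset(
    configs: DonorConfig | Sequence[DonorConfig],
    amplicons: Mapping[tuple[str, str], Amplicon],
    seed: int,
) -> SimulatedDataset:
    """Simulate a full clone dataset for one or more donors.

    ``amplicons`` maps (region, strand) to the strand-resolved
    :class:`Amplicon`.  Produces ``clones_per_group`` FASTA records and
    sample-sheet rows per (donor, population, region, strand) group;
    byte-identical for identical (configs, seed).
    """
    if isinstance(configs, DonorConfig):
        configs = (configs,)
    configs = tuple(configs)
    clones: list[tuple[str, str]] = []
    rows = []
    states: dict[tuple[str, str, str, str], np.ndarray] = {}
    inactive_x: dict[tuple[str, str, str, str], np.ndarray] = {}

    for cfg in configs:
        for pop, region, strand in cfg.group_keys():
            profile = cfg.profiles[(pop, region, strand)]
            if (region, strand) not in amplicons:
                raise KeyError(f"no amplicon for region {region!r} strand {strand!r}")
            amp = amplicons[(region, strand)]
            rng = _group_rng(seed, (cfg.donor_id, pop, region, strand))
            mosaic = cfg.mosaic_for(pop, region, strand)
            group_states = np.empty((cfg.clones_per_group, amp.n_cpg), dtype=bool)
            group_inactive = np.zeros(cfg.clones_per_group, dtype=bool)
            for i in range(cfg.clones_per_group):
                use_profile = profile
                if mosaic is not None and rng.random() < mosaic.fraction_inactive:
                    use_profile = mosaic.inactive_profiles[(region, strand)]
                    group_inactive[i] = True
                st, seq = simulate_clone(
                    use_profile, amp, cfg.conversion, cfg.seq_error_rate, rng
                )
                group_states[i] = st
                cid = _clone_id(cfg.donor_id, pop, region, strand, i)
                clones.append((cid, seq))
                rows.append(
                    {
                        "clone_id": cid,
                        "donor": cfg.donor_id,
                        "sex": cfg.sex,
                        "population": pop,
                        "region": region,
                        "strand": strand,
                    }
                )
            key = (cfg.donor_id, pop, region, strand)
            states[key] = group_states
            inactive_x[key] = group_inactive

    sheet = pd.DataFrame(
        rows, columns=["clone_id", "donor", "sex", "population", "region", "strand"]
    )
    truth = SimulationTruth(states=states, inactive_x=inactive_x, configs=configs, seed=int(seed))
    return SimulatedDataset(
        clones=clones, sample_sheet=sheet, truth=truth, amplicons=dict(amplicons)
    )


# ---------------------------------------------------------------------------
# Synthetic reference sequences and canned study scenarios
# ---------------------------------------------------------------------------

def synthetic_reference(name: str, n_cpg: int, spacing: int = 28) -> str:
    """Deterministic synthetic genomic top-strand sequence with ``n_cpg`` CpGs.

    Synthetic stand-in for the assay's amplicon sequences (which are
    user-supplied in real runs): random inter-CpG segments free of CG
    dinucleotides, with plenty of non-CpG cytosines so conversion QC has
    assessable sites.  Deterministic per (name, n_cpg, spacing).
    """
    digest = hashlib.sha256(f"synthref|{name}|{n_cpg}|{spacing}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    bases = "ACGT"
    not_after_c = "ACT"  # avoid creating CG inside segments

    def segment(length: int) -> str:
        out = []
        prev = ""
        for _ in range(length):
            pool = not_after_c if prev == "C" else bases
            prev = pool[rng.integers(len(pool))]
            out.append(prev)
        return "".join(out)

    parts = [segment(spacing)]
    for _ in range(n_cpg):
        parts.append("CG")
        parts.append(segment(spacing))
    return "".join(parts)


def _region_amplicons(regions: Mapping[str, Sequence[str]]) -> dict[tuple[str, str], Amplicon]:
    """Build strand-resolved amplicons for ``region -> strands`` requests."""
    out: dict[tuple[str, str], Amplicon] = {}
    for region, strands in regions.items():
        genomic = synthetic_reference(region, REGION_CPG_COUNTS[region])
        for strand in strands:
            out[(region, strand)] = Amplicon.from_genomic(
                region,
                genomic,
                assayed_strand=strand,
                gene_strand_label="coding" if region.startswith("FOXP3") and strand == BOTTOM else None,
            )
    return out


SCENARIOS = ("conventional_male", "hemimethylated_donor", "xi_female", "null_pair")

# Generating probabilities (study conditions): Treg TSDR nearly fully
# demethylated, Tcon heavily methylated, CD34 methylated; the
# hemimethylated donor keeps the coding (bottom) strand fully methylated
# in every population while the top strand follows the conventional
# pattern.
_P_TREG_LOW = 0.02
_P_TCON_HIGH = 0.95
_P_CD34 = 0.90
_SCENARIO_REGION = "FOXP3_TSDR"


def _flat_profile(region: str, strand: str, p: float) -> MethylationProfile:
    n = REGION_CPG_COUNTS[region]
    return MethylationProfile(region=region, strand=strand, p_meth=(p,) * n)


def _conventional_p(pop: str) -> float:
    if pop == "Tcon":
        return _P_TCON_HIGH
    if pop == "CD34":
        return _P_CD34
    return _P_TREG_LOW


def scenario_amplicons(name: str) -> dict[tuple[str, str], Amplicon]:
    """Strand-resolved amplicons backing a canned scenario."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    strands = (TOP,) if name == "null_pair" else (TOP, BOTTOM)
    return _region_amplicons({_SCENARIO_REGION: strands})


def make_scenario(name: str, donor_id: str | None = None, sex: str | None = None) -> DonorConfig:
    """Canned single-donor configurations for the assay's headline settings.

    ``conventional_male``: Treg subsets demethylated, Tcon methylated,
    identically on both strands.  ``hemimethylated_donor``: bottom
    (coding) strand fully methylated in all populations, top strand
    conventional.  ``xi_female``: 50:50 clone-level mosaic of the
    conventional profile with a fully methylated inactive-X profile.
    ``null_pair``: two populations with element-wise identical profiles.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    region = _SCENARIO_REGION
    if sex is None:
        sex = "F" if name == "xi_female" else "M"
    if donor_id is None:
        donor_id = f"{sex}1"

    profiles: dict[tuple[str, str, str], MethylationProfile] = {}
    xi = None
    if name == "null_pair":
        pops = ("CD45RA-CD15s+", "Tcon")
        for pop in pops:
            profiles[(pop, region, TOP)] = _flat_profile(region, TOP, 0.5)
    else:
        pops = POPULATIONS
        for pop in pops:
            for strand in (TOP, BOTTOM):
                if name == "hemimethylated_donor" and strand == BOTTOM:
                    p = 1.0
                else:
                    p = _conventional_p(pop)
                profiles[(pop, region, strand)] = _flat_profile(region, strand, p)
        if name == "xi_female":
            xi = XiMosaic(
                fraction_inactive=0.5,
                inactive_profiles={
                    (region, s): _flat_profile(region, s, 1.0) for s in (TOP, BOTTOM)
                },
            )

    return DonorConfig(
        donor_id=donor_id,
        sex=sex,
        populations=pops,
        profiles=profiles,
        xi_mosaic=xi,
    )


def make_study(name: str, n_donors: int = 6) -> tuple[list[DonorConfig], dict[tuple[str, str], Amplicon]]:
    """A multi-donor study under one scenario, plus its amplicons."""
    sex = "F" if name == "xi_female" else "M"
    configs = [
        make_scenario(name, donor_id=f"{sex}{i + 1}", sex=sex) for i in range(n_donors)
    ]
    return configs, scenario_amplicons(name)


def config_to_json(configs: DonorConfig | Sequence[DonorConfig], path: str | Path) -> None:
    """Serialize donor configurations as JSON (for run manifests)."""
    if isinstance(configs, DonorConfig):
        configs = (configs,)

    def encode(cfg: DonorConfig) -> dict:
        return {
            "donor_id": cfg.donor_id,
            "sex": cfg.sex,
            "populations": list(cfg.populations),
            "clones_per_group": cfg.clones_per_group,
            "seq_error_rate": cfg.seq_error_rate,
            "conversion": {
                "conversion_rate": cfg.conversion.conversion_rate,
                "protection_rate": cfg.conversion.protection_rate,
            },
            "profiles": [
                {
                    "population": pop,
                    "region": region,
                    "strand": strand,
                    "p_meth": list(prof.p_meth),
                    "correlation_mode": prof.correlation_mode,
                }
                for (pop, region, strand), prof in cfg.profiles.items()
            ],
            "xi_mosaic": None
            if cfg.xi_mosaic is None
            else {
                "fraction_inactive": cfg.xi_mosaic.fraction_inactive,
                "inactive_profiles": [
                    {"region": r, "strand": s, "p_meth": list(p.p_meth)}
                    for (r, s), p in cfg.xi_mosaic.inactive_profiles.items()
                ],
            },
        }

    with open(path, "w") as fh:
        json.dump([encode(c) for c in configs], fh, indent=2)
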