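"""Synthetic drinking-water metagenome studies with planted structure.

The generator emulates the data products of a comparative survey of
disinfected (D, chlorinated) versus non-disinfected (ND) drinking water
distribution systems: per-system co-assemblies with scaffold coverage under
sample and negative-control read sets, SSU rRNA hits, ORF->KO annotations, a
KEGG-style module catalog, MAGs with per-sample breadth of coverage, a water
chemistry table, and per-sample sequence sets for sketching. Ground truth
(contaminant flags, taxon group enrichment, intended MAG categories) is
carried alongside so every downstream stage can be validated exactly.

Planted structure
-----------------
* Taxon abundances are log-normal per sample, with group-specific mean shifts
  for enriched taxa. In disinfected samples the shift scales with that
  sample's chlorine concentration, so chlorine concentration - not just group
  membership - drives community distances. Non-disinfected samples draw with
  a larger dispersion (more variable communities).
* Contaminant taxa contribute coverage to negative controls in every study
  and to true samples only at a configurable leak rate (0 by default:
  pure-contaminant mode).
* Chlorine and phosphate are exactly 0 in every ND sample.
* MAG-founding taxa follow hard presence patterns (D-only, ND-only,
  ubiquitous, rare) so the intended detection category is recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .decontam import ScaffoldTable
from .function import ModuleCatalog, format_module_definition
from .mags import MAGRecord
from .taxonomy import HIT_COLUMNS

__all__ = [
    "EnvVar",
    "StudyConfig",
    "StudyTruth",
    "SyntheticStudy",
    "default_env_vars",
    "generate_study",
    "generate_sample_sequences",
    "write_study",
    "read_study",
]

# fixed per-table child-seed offsets: adding a table never perturbs the others
_STREAM_ENV = 1
_STREAM_ABUND = 2
_STREAM_SCAFFOLD = 3
_STREAM_SSU = 4
_STREAM_KO = 5
_STREAM_MAG = 6
_STREAM_REF = 7
_STREAM_CONTAM = 8

ROLE_MAG_D_ONLY = "mag_d_only"
ROLE_MAG_ND_ONLY = "mag_nd_only"
ROLE_MAG_BOTH = "mag_both"
ROLE_MAG_OTHER = "mag_other"
ROLE_D_ENRICHED = "d_enriched"
ROLE_ND_ENRICHED = "nd_enriched"
ROLE_NEUTRAL = "neutral"

_LINEAGES = [
    ("bacteria", "Bacteria;Proteobacteria;Alphaproteobacteria;Sphingomonadales;Sphingomonadaceae;Sphingomonas"),
    ("bacteria", "Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales;Pseudomonadaceae;Pseudomonas"),
    ("bacteria", "Bacteria;Nitrospirota;Nitrospiria;Nitrospirales;Nitrospiraceae;Nitrospira"),
    ("bacteria", "Bacteria;Planctomycetota;Planctomycetia;Gemmatales;Gemmataceae;Gemmata"),
    ("bacteria", "Bacteria;Bacteroidota;Bacteroidia;Chitinophagales;Chitinophagaceae;Sediminibacterium"),
    ("bacteria", "Bacteria;Actinobacteriota;Actinomycetia;Mycobacteriales;Mycobacteriaceae;Mycobacterium"),
    ("archaea", "Archaea;Nitrososphaerota;Nitrososphaeria;Nitrosopumilales;Nitrosopumilaceae;Nitrosopumilus"),
    ("eukaryota", "Eukaryota;Amoebozoa;Discosea;Centramoebida;Acanthamoebidae;Acanthamoeba"),
]
_CONTAM_LINEAGES = [
    ("bacteria", "Bacteria;Actinobacteriota;Actinomycetia;Propionibacteriales;Propionibacteriaceae;Cutibacterium"),
    ("bacteria", "Bacteria;Firmicutes;Bacilli;Staphylococcales;Staphylococcaceae;Staphylococcus"),
    ("bacteria", "Bacteria;Proteobacteria;Gammaproteobacteria;Burkholderiales;Comamonadaceae;Delftia"),
    ("bacteria", "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Methylobacteriaceae;Methylobacterium"),
]


@dataclass(frozen=True)
class EnvVar:
    """Group-conditional generator for one water-chemistry variable.

    A variable with mean 0 and SD 0 in a group is *exactly* 0 there (no
    measurable residual), not a degenerate normal draw.
    """

    name: str
    unit: str
    mean_d: float
    sd_d: float
    mean_nd: float
    sd_nd: float


def default_env_vars() -> list[EnvVar]:
    """Nine water-chemistry variables typical of distribution-system surveys.

    Chlorine averages 0.37 mg Cl2/l in disinfected systems and is exactly 0
    without a residual; phosphate (dosed for corrosion control alongside
    chlorine) behaves likewise; disinfected samples run ~5 degC warmer.
    """
    return [
        EnvVar("temperature", "degC", 16.0, 2.0, 11.0, 2.0),
        EnvVar("ph", "pH", 7.8, 0.2, 7.9, 0.2),
        EnvVar("conductivity", "uS/cm", 480.0, 120.0, 330.0, 100.0),
        EnvVar("do", "mg/l", 9.5, 1.0, 9.8, 1.0),
        EnvVar("chlorine", "mg Cl2/l", 0.37, 0.15, 0.0, 0.0),
        EnvVar("phosphate", "mg PO4/l", 2.3, 0.5, 0.0, 0.0),
        EnvVar("toc", "mg/l", 1.6, 0.5, 1.4, 0.5),
        EnvVar("ammonium", "mg N/l", 0.05, 0.02, 0.04, 0.02),
        EnvVar("nitrate", "mg N/l", 1.2, 0.4, 1.0, 0.4),
    ]


@dataclass
class StudyConfig:
    """Parameters of a synthetic study.

    Defaults describe a desk-scale analogue of a two-country survey: six
    distribution systems (three chlorinated, three without a residual), three
    sampling locations each, two sequenced negative controls, and strong
    chlorine-driven community structure.
    """

    n_systems_d: int = 3
    n_systems_nd: int = 3
    samples_per_system: int = 3
    n_taxa: int = 24
    n_contaminant_taxa: int = 4
    scaffolds_per_taxon: int = 8
    scaffold_len_range: tuple[int, int] = (1000, 5000)
    mean_depth: float = 10.0
    abundance_dispersion: float = 0.4  # log-scale SD in D samples
    nd_dispersion_factor: float = 2.0  # ND communities are more variable
    group_effect: float = 2.5  # log-scale shift for enriched taxa
    n_kos: int = 120
    n_modules: int = 12
    kos_per_taxon: int = 25
    read_length: int = 250
    reads_per_sample: int = 200_000
    n_negative_controls: int = 2
    contaminant_leak_rate: float = 0.0  # pure-contaminant mode
    coverage_noise_sd: float = 0.2  # multiplicative log-normal noise on depth
    ncd_sample: float = 0.3  # depth SD / mean for sample read sets
    ncd_control: float = 0.6  # contaminant coverage is patchier
    nc_background: float = 0.25  # extra NC coverage beyond contaminant reads
    reference_length: int = 20_000
    env_vars: list[EnvVar] = field(default_factory=default_env_vars)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_systems_d", "n_systems_nd", "samples_per_system", "n_taxa",
            "scaffolds_per_taxon", "n_kos", "n_modules", "kos_per_taxon",
            "read_length", "reads_per_sample", "n_negative_controls",
            "reference_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_contaminant_taxa < 0:
            raise ValueError("n_contaminant_taxa must be >= 0")
        if self.n_taxa < 12:
            raise ValueError("need at least 12 taxa to plant all MAG categories")
        lo, hi = self.scaffold_len_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid scaffold length range")


@dataclass
class StudyTruth:
    """Ground truth planted by the generator."""

    scaffolds: pd.DataFrame  # index scaffold_id: taxon, contaminant (bool)
    taxa: pd.DataFrame  # index taxon: role, contaminant (bool)
    mags: pd.DataFrame  # index mag_id: taxon, intended_category


@dataclass
class SyntheticStudy:
    config: StudyConfig
    samples: pd.DataFrame  # index sample_id: system, group, total_reads
    scaffold_table: ScaffoldTable
    ssu_hits: pd.DataFrame
    ko_annotations: pd.DataFrame
    module_catalog: ModuleCatalog
    mags: list[MAGRecord]
    mag_breadth: pd.DataFrame
    mag_reads: pd.DataFrame
    env_table: pd.DataFrame
    truth: StudyTruth
    references: dict[str, str]
    taxon_abundance: pd.DataFrame  # taxon x sample (planting record)

    @property
    def groups(self) -> dict[str, str]:
        return self.samples["group"].to_dict()

    @property
    def sample_systems(self) -> dict[str, str]:
        return self.samples["system"].to_dict()


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _assign_roles(n_taxa: int) -> list[str]:
    roles = [
        ROLE_MAG_D_ONLY, ROLE_MAG_D_ONLY,
        ROLE_MAG_ND_ONLY, ROLE_MAG_ND_ONLY,
        ROLE_MAG_BOTH, ROLE_MAG_BOTH,
        ROLE_MAG_OTHER, ROLE_MAG_OTHER,
    ]
    cycle = [ROLE_D_ENRICHED, ROLE_ND_ENRICHED, ROLE_NEUTRAL]
    roles += [cycle[i % 3] for i in range(n_taxa - len(roles))]
    return roles


def _generate_env(config: StudyConfig, samples: pd.DataFrame) -> pd.DataFrame:
    rng = _rng(config.seed, _STREAM_ENV)
    data = {}
    is_d = (samples["group"] == "D").to_numpy()
    for var in config.env_vars:
        col = np.zeros(len(samples))
        for mask, mean, sd in ((is_d, var.mean_d, var.sd_d), (~is_d, var.mean_nd, var.sd_nd)):
            if mean == 0 and sd == 0:
                col[mask] = 0.0  # exactly no measurable residual
            else:
                col[mask] = np.clip(rng.normal(mean, sd, mask.sum()), 0.0, None)
        data[var.name] = col
    return pd.DataFrame(data, index=samples.index)


def _generate_abundance(
    config: StudyConfig, samples: pd.DataFrame, roles: list[str], env: pd.DataFrame
) -> pd.DataFrame:
    rng = _rng(config.seed, _STREAM_ABUND)
    taxa = [f"T{i:03d}" for i in range(config.n_taxa)]
    n_s = len(samples)
    is_d = (samples["group"] == "D").to_numpy()
    # chlorine dose modulates the planted effect in disinfected samples
    dose = np.ones(n_s)
    if "chlorine" in env.columns and is_d.any():
        mean_cl = float(env.loc[samples.index[is_d], "chlorine"].mean())
        if mean_cl > 0:
            dose = np.where(is_d, env["chlorine"].to_numpy() / mean_cl, 1.0)
    base_mu = rng.normal(0.0, 0.5, config.n_taxa)
    half = config.group_effect / 2.0
    A = np.zeros((config.n_taxa, n_s))
    disp = np.where(is_d, config.abundance_dispersion,
                    config.abundance_dispersion * config.nd_dispersion_factor)
    for t, role in enumerate(roles):
        mu = base_mu[t]
        if role in (ROLE_MAG_D_ONLY, ROLE_MAG_ND_ONLY, ROLE_MAG_BOTH, ROLE_MAG_OTHER):
            mu = abs(mu) + 0.5  # MAG founders stay comfortably detectable
        shift = np.zeros(n_s)
        if role in (ROLE_D_ENRICHED, ROLE_MAG_D_ONLY):
            shift = np.where(is_d, half * dose, -half)
        elif role in (ROLE_ND_ENRICHED, ROLE_MAG_ND_ONLY):
            shift = np.where(is_d, -half * dose, half)
        logs = rng.normal(mu + shift, disp)
        A[t] = np.exp(logs)
        if role == ROLE_MAG_D_ONLY:
            A[t, ~is_d] = 0.0
        elif role == ROLE_MAG_ND_ONLY:
            A[t, is_d] = 0.0
        elif role == ROLE_MAG_OTHER:
            mask = np.zeros(n_s, dtype=bool)
            mask[0] = True  # present in a single sample -> below 20% frequency
            A[t, ~mask] = 0.0
    return pd.DataFrame(A, index=pd.Index(taxa, name="taxon"), columns=list(samples.index))


def _taxon_lineage(idx: int, contaminant: bool) -> tuple[str, str]:
    pool = _CONTAM_LINEAGES if contaminant else _LINEAGES
    domain, lineage = pool[idx % len(pool)]
    parts = lineage.split(";")
    parts[-1] = f"{parts[-1]}_{idx:03d}"
    return domain, ";".join(parts)


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate a complete synthetic study; identical configs (including seed)
    yield byte-identical studies after serialization."""
    systems = [f"D{i + 1}" for i in range(config.n_systems_d)] + [
        f"ND{i + 1}" for i in range(config.n_systems_nd)
    ]
    rows = []
    for sys_id in systems:
        group = "D" if sys_id.startswith("D") and not sys_id.startswith("ND") else "ND"
        for k in range(config.samples_per_system):
            rows.append(
                {
                    "sample_id": f"{sys_id}-{k + 1}",
                    "system": sys_id,
                    "group": group,
                    "total_reads": config.reads_per_sample,
                }
            )
    samples = pd.DataFrame(rows).set_index("sample_id")
    controls = [f"NC{j + 1}" for j in range(config.n_negative_controls)]

    env = _generate_env(config, samples)
    roles = _assign_roles(config.n_taxa)
    abundance = _generate_abundance(config, samples, roles, env)
    taxa = list(abundance.index)
    contam_taxa = [f"C{i:02d}" for i in range(config.n_contaminant_taxa)]

    rng_c = _rng(config.seed, _STREAM_CONTAM)
    contam_abund = pd.DataFrame(
        np.exp(rng_c.normal(0.5, 0.5, (config.n_contaminant_taxa, len(controls)))),
        index=pd.Index(contam_taxa, name="taxon"),
        columns=controls,
    )
    leak = pd.DataFrame(
        0.0, index=contam_abund.index, columns=list(samples.index)
    )
    if config.contaminant_leak_rate > 0:
        leak_mask = rng_c.random(leak.shape) < config.contaminant_leak_rate
        leak_vals = np.exp(rng_c.normal(-1.0, 0.5, leak.shape))
        leak[:] = np.where(leak_mask, leak_vals, 0.0)

    # ---- scaffolds per system ------------------------------------------------
    rng_s = _rng(config.seed, _STREAM_SCAFFOLD)
    lo, hi = config.scaffold_len_range
    taxon_gc = {t: g for t, g in zip(taxa, rng_s.uniform(0.35, 0.65, len(taxa)))}
    taxon_gc.update(
        {t: g for t, g in zip(contam_taxa, rng_s.uniform(0.40, 0.60, len(contam_taxa)))}
    )
    meta_rows = []
    cov_rows, cov_sd_rows = [], []
    ccov_rows, ccov_sd_rows, nc_rows = [], [], []
    truth_scaffold_rows = []
    ssu_scaffold_of: dict[tuple[str, str], str] = {}  # (system, taxon) -> scaffold
    scaffolds_of: dict[tuple[str, str], list[str]] = {}
    noise = config.coverage_noise_sd

    def _depth_noise(rng, n):
        return np.exp(rng.normal(0.0, noise, n)) if noise > 0 else np.ones(n)

    for sys_id in systems:
        sys_samples = [s for s in samples.index if samples.loc[s, "system"] == sys_id]
        present = [t for t in taxa if abundance.loc[t, sys_samples].sum() > 0]
        for taxon in present + contam_taxa:
            contaminant = taxon in contam_taxa
            ids = []
            for j in range(config.scaffolds_per_taxon):
                sid = f"{sys_id}_{taxon}_{j:03d}"
                length = int(rng_s.integers(lo, hi + 1))
                if j == 0:
                    length = max(length, 2000)  # SSU-bearing scaffold fits the gene
                gc = float(np.clip(taxon_gc[taxon] + rng_s.normal(0, 0.02), 0.0, 1.0))
                meta_rows.append(
                    {"scaffold_id": sid, "system": sys_id, "length": length, "gc": gc}
                )
                truth_scaffold_rows.append(
                    {"scaffold_id": sid, "taxon": taxon, "contaminant": contaminant}
                )
                ids.append(sid)
                scov = np.zeros(len(samples))
                if not contaminant:
                    a = abundance.loc[taxon, sys_samples].to_numpy()
                    idx = [samples.index.get_loc(s) for s in sys_samples]
                    scov[idx] = a * config.mean_depth * _depth_noise(rng_s, len(idx))
                else:
                    a = leak.loc[taxon].to_numpy()
                    scov = a * config.mean_depth
                cov_rows.append(scov)
                cov_sd_rows.append(scov * config.ncd_sample)
                ccov = np.zeros(len(controls))
                ncov = np.zeros(len(controls))
                if contaminant:
                    ccov = (
                        contam_abund.loc[taxon].to_numpy()
                        * config.mean_depth
                        * _depth_noise(rng_s, len(controls))
                    )
                    ncov = ccov * (1.0 + config.nc_background)
                ccov_rows.append(ccov)
                ccov_sd_rows.append(ccov * config.ncd_control)
                nc_rows.append(ncov)
            scaffolds_of[(sys_id, taxon)] = ids
            ssu_scaffold_of[(sys_id, taxon)] = ids[0]

    meta = pd.DataFrame(meta_rows).set_index("scaffold_id")
    scaffold_table = ScaffoldTable(
        meta=meta,
        cov=pd.DataFrame(cov_rows, index=meta.index, columns=list(samples.index)),
        cov_sd=pd.DataFrame(cov_sd_rows, index=meta.index, columns=list(samples.index)),
        contam_cov=pd.DataFrame(ccov_rows, index=meta.index, columns=controls),
        contam_cov_sd=pd.DataFrame(ccov_sd_rows, index=meta.index, columns=controls),
        nc_cov=pd.DataFrame(nc_rows, index=meta.index, columns=controls),
        sample_systems=samples["system"].to_dict(),
    )

    # ---- SSU hits ------------------------------------------------------------
    rng_ssu = _rng(config.seed, _STREAM_SSU)
    hit_rows = []
    all_taxa_idx = {t: i for i, t in enumerate(taxa)}
    all_taxa_idx.update({t: i for i, t in enumerate(contam_taxa)})
    for (sys_id, taxon), sid in sorted(ssu_scaffold_of.items()):
        contaminant = taxon in contam_taxa
        domain, lineage = _taxon_lineage(all_taxa_idx[taxon], contaminant)
        gene_len = int(rng_ssu.integers(1250, 1551))
        hit_rows.append(
            {
                "hit_id": f"{sid}_ssu1",
                "scaffold_id": sid,
                "domain": domain,
                "lineage": lineage,
                "align_len": int(rng_ssu.integers(400, gene_len + 1)),
                "evalue": float(10.0 ** -rng_ssu.uniform(10, 40)),
                "gene_len": gene_len,
            }
        )
    # decoys exercising the filters and the longest-per-scaffold rule
    if hit_rows:
        first = hit_rows[0]
        hit_rows.append(
            {**first, "hit_id": first["scaffold_id"] + "_ssu2",
             "gene_len": first["gene_len"] - 300,
             "align_len": max(100, first["align_len"] - 300)}
        )
        hit_rows.append(
            {**first, "hit_id": first["scaffold_id"] + "_ssu3",
             "align_len": 80}  # fails the >= 100 bp alignment filter
        )
        hit_rows.append(
            {**first, "hit_id": first["scaffold_id"] + "_ssu4",
             "evalue": 1e-4}  # fails the < 1e-5 e-value filter
        )
    ssu_hits = pd.DataFrame(hit_rows, columns=HIT_COLUMNS)

    # ---- KO annotations and module catalog -----------------------------------
    rng_ko = _rng(config.seed, _STREAM_KO)
    ko_pool = [f"K{10000 + i}" for i in range(config.n_kos)]
    n_grp = max(4, config.n_kos // 6)
    d_kos = ko_pool[:n_grp]
    nd_kos = ko_pool[n_grp : 2 * n_grp]
    shared_kos = ko_pool[2 * n_grp :]
    taxon_kos: dict[str, list[str]] = {}
    for t, role in zip(taxa, roles):
        k_total = min(config.kos_per_taxon, config.n_kos)
        if role in (ROLE_D_ENRICHED, ROLE_MAG_D_ONLY):
            special = d_kos
        elif role in (ROLE_ND_ENRICHED, ROLE_MAG_ND_ONLY):
            special = nd_kos
        else:
            special = []
        n_special = min(len(special), max(0, k_total // 3))
        chosen = list(rng_ko.choice(special, n_special, replace=False)) if n_special else []
        n_shared = min(len(shared_kos), k_total - len(chosen))
        chosen += list(rng_ko.choice(shared_kos, n_shared, replace=False))
        taxon_kos[t] = sorted(chosen)
    for t in contam_taxa:
        n_shared = min(len(shared_kos), max(4, config.kos_per_taxon // 2))
        taxon_kos[t] = sorted(rng_ko.choice(shared_kos, n_shared, replace=False))

    ann_rows = []
    for (sys_id, taxon), ids in sorted(scaffolds_of.items()):
        for n, ko in enumerate(taxon_kos[taxon]):
            host = ids[n % len(ids)]
            ann_rows.append(
                {"orf_id": f"{host}_orf{n:03d}", "scaffold_id": host, "ko_id": ko}
            )
    ko_annotations = pd.DataFrame(ann_rows, columns=["orf_id", "scaffold_id", "ko_id"])

    defs: dict[str, str] = {}
    pools = {"d": d_kos, "nd": nd_kos, "shared": shared_kos}
    for m in range(config.n_modules):
        if m < 3:
            pool = pools["d"]
        elif m < 6:
            pool = pools["nd"]
        else:
            pool = pools["shared"]
        n_blocks = int(rng_ko.integers(2, 5))
        blocks = []
        for b in range(n_blocks):
            n_alt = int(rng_ko.integers(1, 3))
            members = rng_ko.choice(pool, min(n_alt + 1, len(pool)), replace=False)
            if n_alt == 1:
                if rng_ko.random() < 0.3 and len(members) >= 2:
                    blocks.append([tuple(sorted(members[:2]))])  # complex K+K
                else:
                    blocks.append([(members[0],)])
            else:
                blocks.append([(m_,) for m_ in sorted(members[:n_alt])])
        defs[f"M{m + 1:05d}"] = format_module_definition(blocks)
    module_catalog = ModuleCatalog.from_definitions(defs)

    # ---- MAGs ----------------------------------------------------------------
    rng_mag = _rng(config.seed, _STREAM_MAG)
    intended = {
        ROLE_MAG_D_ONLY: "D-only",
        ROLE_MAG_ND_ONLY: "ND-only",
        ROLE_MAG_BOTH: "both",
        ROLE_MAG_OTHER: "other",
    }
    mag_records: list[MAGRecord] = []
    mag_truth_rows = []
    breadth_rows, reads_rows = [], []
    mag_ids = []
    founders = [(t, r) for t, r in zip(taxa, roles) if r in intended]
    for i, (taxon, role) in enumerate(founders):
        rep_sys = next(
            sys_id for sys_id in systems if (sys_id, taxon) in scaffolds_of
            and abundance.loc[taxon, [s for s in samples.index
                                      if samples.loc[s, "system"] == sys_id]].sum() > 0
        )
        members = scaffolds_of[(rep_sys, taxon)]
        length = int(meta.loc[members, "length"].sum())
        mag_id = f"MAG{i + 1:03d}"
        mag_records.append(
            MAGRecord(
                mag_id=mag_id,
                length=length,
                completeness=float(rng_mag.uniform(60, 95)),
                redundancy=float(rng_mag.uniform(0, 8)),
                member_scaffolds=frozenset(members),
                taxonomy=_taxon_lineage(all_taxa_idx[taxon], False)[1],
            )
        )
        mag_truth_rows.append(
            {"mag_id": mag_id, "taxon": taxon, "intended_category": intended[role]}
        )
        depth = abundance.loc[taxon].to_numpy() * config.mean_depth
        breadth_rows.append(1.0 - np.exp(-depth))
        reads_rows.append(depth * length / config.read_length)
        mag_ids.append(mag_id)
    # two quality-control decoys that must be discarded upstream of detection
    for j, (comp, red) in enumerate([(45.0, 5.0), (80.0, 12.0)]):
        taxon = taxa[8 + j]
        rep_sys = systems[0]
        members = scaffolds_of.get((rep_sys, taxon))
        if members:
            mag_id = f"MAGX{j + 1}"
            mag_records.append(
                MAGRecord(
                    mag_id=mag_id,
                    length=int(meta.loc[members, "length"].sum()),
                    completeness=comp,
                    redundancy=red,
                    member_scaffolds=frozenset(members),
                )
            )
            mag_truth_rows.append(
                {"mag_id": mag_id, "taxon": taxon, "intended_category": "qc_fail"}
            )
            depth = abundance.loc[taxon].to_numpy() * config.mean_depth
            breadth_rows.append(1.0 - np.exp(-depth))
            reads_rows.append(depth * meta.loc[members, "length"].sum() / config.read_length)
            mag_ids.append(mag_id)
    mag_breadth = pd.DataFrame(breadth_rows, index=mag_ids, columns=list(samples.index))
    mag_reads = pd.DataFrame(reads_rows, index=mag_ids, columns=list(samples.index))

    # ---- reference sequences -------------------------------------------------
    rng_ref = _rng(config.seed, _STREAM_REF)
    references = {}
    for taxon in taxa + contam_taxa:
        gc = taxon_gc[taxon]
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        arr = rng_ref.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                             config.reference_length, p=p)
        references[taxon] = arr.tobytes().decode("ascii")

    truth = StudyTruth(
        scaffolds=pd.DataFrame(truth_scaffold_rows).set_index("scaffold_id"),
        taxa=pd.DataFrame(
            {"role": roles + ["contaminant"] * len(contam_taxa),
             "contaminant": [False] * len(taxa) + [True] * len(contam_taxa)},
            index=pd.Index(taxa + contam_taxa, name="taxon"),
        ),
        mags=pd.DataFrame(mag_truth_rows).set_index("mag_id"),
    )
    return SyntheticStudy(
        config=config,
        samples=samples,
        scaffold_table=scaffold_table,
        ssu_hits=ssu_hits,
        ko_annotations=ko_annotations,
        module_catalog=module_catalog,
        mags=mag_records,
        mag_breadth=mag_breadth,
        mag_reads=mag_reads,
        env_table=env,
        truth=truth,
        references=references,
        taxon_abundance=abundance,
    )


def generate_sample_sequences(
    study: SyntheticStudy,
    sample_id: str,
    seed: int = 0,
    n_fragments: int = 400,
    fragment_length: int = 300,
) -> list[str]:
    """Draw sequence fragments from taxon references in proportion to the
    sample's taxon abundances.

    The draw depends only on the abundance vector and ``seed``: two samples
    with identical abundance vectors and the same seed yield identical
    fragment multisets.
    """
    if sample_id not in study.samples.index:
        raise KeyError(f"unknown sample {sample_id!r}")
    ab = study.taxon_abundance[sample_id]
    ab = ab[ab > 0]
    if ab.empty:
        return []
    rng = np.random.default_rng(seed)
    probs = (ab / ab.sum()).to_numpy()
    taxa = list(ab.index)
    picks = rng.choice(len(taxa), n_fragments, p=probs)
    frags = []
    for t_idx in picks:
        ref = study.references[taxa[t_idx]]
        start = int(rng.integers(0, max(1, len(ref) - fragment_length + 1)))
        frags.append(ref[start : start + fragment_length])
    return frags


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_study(
    study: SyntheticStudy, directory, write_fasta: bool = True, seq_seed: int = 0
) -> dict[str, int]:
    """Write the study as TSV tables, FASTA files and a flat-text manifest.

    Returns the manifest mapping (file name -> row/record count). Ground
    truth goes to separate ``truth_*.tsv`` files so analysis code can be run
    blind against the main tables.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    st = study.scaffold_table
    frames = {
        "samples.tsv": study.samples,
        "scaffolds.tsv": st.meta,
        "coverage.tsv": st.cov,
        "coverage_sd.tsv": st.cov_sd,
        "contaminant_coverage.tsv": st.contam_cov,
        "contaminant_coverage_sd.tsv": st.contam_cov_sd,
        "negative_control_coverage.tsv": st.nc_cov,
        "ssu_hits.tsv": study.ssu_hits,
        "ko_annotations.tsv": study.ko_annotations,
        "mag_breadth.tsv": study.mag_breadth,
        "mag_reads.tsv": study.mag_reads,
        "env.tsv": study.env_table,
        "taxon_abundance.tsv": study.taxon_abundance,
        "truth_scaffolds.tsv": study.truth.scaffolds,
        "truth_taxa.tsv": study.truth.taxa,
        "truth_mags.tsv": study.truth.mags,
    }
    manifest: dict[str, int] = {}
    for name, frame in frames.items():
        indexed = name not in ("ssu_hits.tsv", "ko_annotations.tsv")
        frame.to_csv(directory / name, sep="\t", index=indexed)
        manifest[name] = len(frame)
    mag_df = pd.DataFrame(
        [
            {
                "mag_id": m.mag_id,
                "length": m.length,
                "completeness": m.completeness,
                "redundancy": m.redundancy,
                "member_scaffolds": ",".join(sorted(m.member_scaffolds)),
                "taxonomy": m.taxonomy or "",
            }
            for m in study.mags
        ]
    )
    mag_df.to_csv(directory / "mags.tsv", sep="\t", index=False)
    manifest["mags.tsv"] = len(mag_df)
    study.module_catalog.write(directory / "modules.tsv")
    manifest["modules.tsv"] = len(study.module_catalog)

    ref_records = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in study.references.items()
    ]
    SeqIO.write(ref_records, directory / "references.fasta", "fasta")
    manifest["references.fasta"] = len(ref_records)
    if write_fasta:
        reads_dir = directory / "reads"
        reads_dir.mkdir(exist_ok=True)
        for sample_id in study.samples.index:
            frags = generate_sample_sequences(study, sample_id, seed=seq_seed)
            records = [
                SeqRecord(Seq(f), id=f"{sample_id}_frag{i:05d}", description="")
                for i, f in enumerate(frags)
            ]
            SeqIO.write(records, reads_dir / f"{sample_id}.fasta", "fasta")
            manifest[f"reads/{sample_id}.fasta"] = len(records)

    with open(directory / "manifest.txt", "w") as fh:
        fh.write(f"seed={study.config.seed}\n")
        for name in sorted(manifest):
            fh.write(f"{name}={manifest[name]}\n")
    return manifest


def read_study(directory) -> SyntheticStudy:
    """Reconstruct a study written by :func:`write_study` (lossless for every
    table; the generator config is not recoverable beyond its seed and is
    replaced by a default-valued config carrying that seed)."""
    directory = Path(directory)

    def _read(name, index_col=0):
        return pd.read_csv(directory / name, sep="\t", index_col=index_col)

    samples = _read("samples.tsv")
    meta = _read("scaffolds.tsv")
    st = ScaffoldTable(
        meta=meta,
        cov=_read("coverage.tsv"),
        cov_sd=_read("coverage_sd.tsv"),
        contam_cov=_read("contaminant_coverage.tsv"),
        contam_cov_sd=_read("contaminant_coverage_sd.tsv"),
        nc_cov=_read("negative_control_coverage.tsv"),
        sample_systems=samples["system"].to_dict(),
    )
    ssu_hits = pd.read_csv(directory / "ssu_hits.tsv", sep="\t")
    ko_annotations = pd.read_csv(directory / "ko_annotations.tsv", sep="\t")
    mag_df = pd.read_csv(directory / "mags.tsv", sep="\t")
    mags = [
        MAGRecord(
            mag_id=row["mag_id"],
            length=int(row["length"]),
            completeness=float(row["completeness"]),
            redundancy=float(row["redundancy"]),
            member_scaffolds=frozenset(
                str(row["member_scaffolds"]).split(",")
                if isinstance(row["member_scaffolds"], str) and row["member_scaffolds"]
                else []
            ),
            taxonomy=row["taxonomy"] if isinstance(row["taxonomy"], str) and row["taxonomy"] else None,
        )
        for _, row in mag_df.iterrows()
    ]
    references = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(directory / "references.fasta", "fasta")
    }
    seed = 0
    with open(directory / "manifest.txt") as fh:
        for line in fh:
            if line.startswith("seed="):
                seed = int(line.strip().split("=", 1)[1])
    truth = StudyTruth(
        scaffolds=_read("truth_scaffolds.tsv"),
        taxa=_read("truth_taxa.tsv"),
        mags=_read("truth_mags.tsv"),
    )
    return SyntheticStudy(
        config=StudyConfig(seed=seed),
        samples=samples,
        scaffold_table=st,
        ssu_hits=ssu_hits,
        ko_annotations=ko_annotations,
        module_catalog=ModuleCatalog.read(directory / "modules.tsv"),
        mags=mags,
        mag_breadth=_read("mag_breadth.tsv"),
        mag_reads=_read("mag_reads.tsv"),
        env_table=_read("env.tsv"),
        truth=truth,
        references=references,
        taxon_abundance=_read("taxon_abundance.tsv"),
    )
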