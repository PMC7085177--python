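"""End-to-end analysis of a study: decontaminate, profile, compare.

Mirrors the stages of a comparative drinking-water metagenome analysis:

1. discard scaffolds shorter than 500 bp, then classify the rest against the
   negative controls and keep only true scaffolds;
2. SSU-based taxonomic profiles per sample;
3. KO retention filters, KO abundance table, module profiles;
4. Bray-Curtis distances between samples on KO RPKM, BioEnv environmental
   fitting, and a permutation test for the disinfected / non-disinfected
   group effect;
5. MAG quality control, breadth-based detection, categorization and RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from skbio import DistanceMatrix

from . import decontam, distance, function, mags, taxonomy
from .simulate import SyntheticStudy

__all__ = ["StudyAnalysis", "analyze_study"]


@dataclass
class StudyAnalysis:
    classification: pd.DataFrame
    true_table: decontam.ScaffoldTable
    assembly_stats: dict[str, decontam.AssemblyStats]
    taxon_profiles: dict[str, taxonomy.TaxonProfile]
    retained_kos: set[tuple[str, str]]
    ko_table: function.KOAbundanceTable
    module_profiles: pd.DataFrame
    filtered_modules: pd.DataFrame
    bray_curtis: DistanceMatrix
    bioenv: distance.BioEnvResult
    group_test: distance.PermTestResult
    mag_qc: list[mags.MAGRecord]
    mag_detection: pd.DataFrame
    mag_categories: pd.DataFrame
    mag_rpkm: pd.DataFrame


def analyze_study(
    study: SyntheticStudy,
    min_scaffold_len: int = 500,
    read_length: float | None = None,
    n_perm: int = 999,
    seed: int = 0,
    phylum_rank: str = "phylum",
) -> StudyAnalysis:
    read_length = float(read_length or study.config.read_length)
    totals = study.samples["total_reads"].astype(float).to_dict()
    groups = study.groups

    # 1. length filter + decontamination
    table = decontam.length_filter(study.scaffold_table, min_scaffold_len)
    classification = decontam.classify_all(table)
    true_table = decontam.true_scaffolds(table, classification)
    stats = {
        system: decontam.assembly_stats(
            true_table.subset(ids.index), totals, read_length
        )
        for system, ids in true_table.meta.groupby("system", sort=False)
    }

    # 2. taxonomic profiles
    hits = taxonomy.filter_ssu_hits(
        study.ssu_hits, true_scaffolds=true_table.scaffold_ids
    )
    hits = taxonomy.dedupe_per_scaffold(hits)
    profiles = {}
    for sample_id in study.samples.index:
        system = study.sample_systems[sample_id]
        sys_hits = hits[
            hits["scaffold_id"].map(true_table.meta["system"]) == system
        ]
        try:
            lineage_profile = taxonomy.ssu_relative_abundance(
                sys_hits, true_table, sample_id, read_length
            )
        except ValueError:
            continue
        profiles[sample_id] = taxonomy.aggregate_by_rank(
            lineage_profile, phylum_rank, split_proteobacteria=True
        )

    # 3. functional profiles
    annotations = study.ko_annotations[
        study.ko_annotations["scaffold_id"].isin(true_table.scaffold_ids)
    ]
    retained = function.filter_kos(annotations, true_table)
    ko_table = function.ko_abundance(
        annotations, true_table, retained, read_length, totals
    )
    mod_profiles = function.module_profiles(study.module_catalog, ko_table)
    filtered_modules = function.filter_modules(mod_profiles)

    # 4. community comparison on KO RPKM
    bc = distance.bray_curtis_matrix(ko_table.rpkm)
    bioenv_res = distance.bioenv(bc, study.env_table)
    group_test = distance.group_distance_test(bc, groups, n_perm=n_perm, seed=seed)

    # 5. MAG analyses
    qc = mags.quality_filter(study.mags)
    qc_ids = [m.mag_id for m in qc]
    detection = mags.detect(study.mag_breadth.loc[qc_ids])
    categories = mags.categorize(detection, groups)
    rpkm = mags.mag_rpkm_table(
        study.mag_reads.loc[qc_ids],
        totals,
        {m.mag_id: m.length for m in qc},
        detection,
    )
    return StudyAnalysis(
        classification=classification,
        true_table=true_table,
        assembly_stats=stats,
        taxon_profiles=profiles,
        retained_kos=retained,
        ko_table=ko_table,
        module_profiles=mod_profiles,
        filtered_modules=filtered_modules,
        bray_curtis=bc,
        bioenv=bioenv_res,
        group_test=group_test,
        mag_qc=qc,
        mag_detection=detection,
        mag_categories=categories,
        mag_rpkm=rpkm,
    )
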