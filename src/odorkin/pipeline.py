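"""End-to-end analysis workflows over peak table + metadata + pedigree.

Two branches mirror the two analytical approaches:

* `similarity_analysis`: blank/rarity filtering, standardization,
  log(x+1) transform, Bray-Curtis distances, then repeated-measures
  ANOSIMs for sex and social group, kin ANOSIMs for the maternal and
  paternal half-sib lines, and Mantel tests of age (and, on the female
  subset, rank) differences against individual-mean profile distances.
  Run on the full data and repeated on the female subset.

* `composition_analysis`: same preprocessing but with the model
  transform, vectorization, the random-slopes mixed model, the omnibus
  and per-predictor likelihood-ratio tests, and the per-compound slope
  table with the strongest-effect selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import compound_lmm, dissimilarity, permutation_tests, preprocess
from .pedigree import PedigreeTable, classify_dyads
from .profile_io import IndividualMetadata, PeakTable

__all__ = ["preprocess_peaks", "similarity_analysis", "composition_analysis"]


def preprocess_peaks(
    peaks: PeakTable,
    blanks: PeakTable | None,
    min_samples: int = 3,
    blank_ratio: float = 1.0,
) -> tuple[PeakTable, preprocess.CompoundFilterReport]:
    """Filter compounds and standardize to percent relative abundances."""
    report = preprocess.filter_compounds(peaks, blanks, min_samples=min_samples,
                                         blank_ratio=blank_ratio)
    retained = preprocess.apply_filter(peaks, report)
    rel = preprocess.standardize(retained)
    return rel, report


def _sample_distance(rel: PeakTable) -> dissimilarity.DissimilarityMatrix:
    return dissimilarity.bray_curtis(preprocess.transform_similarity(rel),
                                     ids=list(rel.sample_ids), level="sample")


def _subset_females(rel: PeakTable, meta: IndividualMetadata) -> tuple[PeakTable, IndividualMetadata]:
    females = meta.individuals.index[meta.individuals["sex"] == "F"].tolist()
    fmeta = meta.subset(females)
    keep = [s for s in rel.sample_ids if s in set(fmeta.sample_map.index)]
    return rel.subset_samples(keep), fmeta


def _attribute_labels(meta: IndividualMetadata, rel: PeakTable, attribute: str
                      ) -> permutation_tests.BlockedLabels:
    block_of = {s: meta.sample_map[s] for s in rel.sample_ids}
    inds = sorted(set(block_of.values()))
    label_of = {i: str(meta.individuals.loc[i, attribute]) for i in inds}
    return permutation_tests.BlockedLabels(list(rel.sample_ids), block_of, label_of)


@dataclass
class SimilarityResults:
    table: pd.DataFrame  # test, subset, statistic, p, n_perm, scheme, n_within, n_between

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def similarity_analysis(
    peaks: PeakTable,
    blanks: PeakTable | None,
    meta: IndividualMetadata,
    ped: PedigreeTable,
    n_perm: int = 999,
    seed: int = 0,
    min_samples: int = 3,
    blank_ratio: float = 1.0,
) -> SimilarityResults:
    """All profile-similarity tests on the full data and the female subset."""
    rel, _ = preprocess_peaks(peaks, blanks, min_samples, blank_ratio)
    rows = []
    rng = np.random.SeedSequence(seed)
    seeds = iter(rng.generate_state(32).tolist())

    for subset in ("all", "females"):
        if subset == "females":
            sub_rel, sub_meta = _subset_females(rel, meta)
        else:
            sub_rel, sub_meta = rel, meta
        D = _sample_distance(sub_rel)
        inds = sorted(set(sub_meta.sample_map[s] for s in sub_rel.sample_ids))
        dyads = classify_dyads(ped, inds)

        def add(test, res):
            stat = res.R if isinstance(res, permutation_tests.AnosimResult) else res.r
            rows.append({
                "test": test, "subset": subset, "statistic": stat, "p": res.p,
                "n_perm": res.n_perm,
                "scheme": getattr(res, "scheme", "mantel"),
                "n_within": getattr(res, "n_within", np.nan),
                "n_between": getattr(res, "n_between", np.nan),
            })

        if subset == "all":
            labels = _attribute_labels(sub_meta, sub_rel, "sex")
            add("anosim_sex", permutation_tests.anosim_test(D, labels, n_perm, next(seeds)))
        labels = _attribute_labels(sub_meta, sub_rel, "group")
        add("anosim_group", permutation_tests.anosim_test(D, labels, n_perm, next(seeds)))
        for line in ("maternal", "paternal"):
            add(f"anosim_{line}_kin",
                permutation_tests.kin_anosim(D, dyads, sub_meta.sample_map, line,
                                             n_perm, next(seeds)))

        means = dissimilarity.individual_mean_profiles(sub_rel, sub_meta)
        Dm = dissimilarity.bray_curtis(
            preprocess.transform_similarity(means),
            ids=list(means.sample_ids), level="individual",
        )
        Dage = dissimilarity.attribute_distance(sub_meta, "age", list(means.sample_ids))
        add("mantel_age", permutation_tests.mantel_test(Dm, Dage, n_perm, next(seeds)))
        if subset == "females":
            Drank = dissimilarity.attribute_distance(sub_meta, "rank", list(means.sample_ids))
            add("mantel_rank", permutation_tests.mantel_test(Dm, Drank, n_perm, next(seeds)))

    return SimilarityResults(pd.DataFrame(rows))


@dataclass
class CompositionResults:
    fit: compound_lmm.LmmFit
    lrt_table: pd.DataFrame  # model, chi_sq, df, p
    slopes: compound_lmm.SlopeTable

    def lrt_to_tsv(self, path) -> None:
        self.lrt_table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def composition_analysis(
    peaks: PeakTable,
    blanks: PeakTable | None,
    meta: IndividualMetadata,
    ped: PedigreeTable,
    subset: str = "all",
    seed: int = 0,
    min_samples: int = 3,
    blank_ratio: float = 1.0,
    transform_order: str = "arcsine_then_log",
) -> CompositionResults:
    """Mixed-model composition analysis on the full data or female subset."""
    rel, _ = preprocess_peaks(peaks, blanks, min_samples, blank_ratio)
    if subset == "females":
        rel, meta = _subset_females(rel, meta)
        predictors: tuple[str, ...] = ("group", "age", "rank")
    elif subset == "all":
        predictors = ("sex", "group", "age")
    else:
        raise ValueError("subset must be 'all' or 'females'")
    y = preprocess.transform_model(rel, order=transform_order)
    transformed = pd.DataFrame(y, index=list(rel.sample_ids), columns=list(rel.compound_ids))
    data = compound_lmm.vectorize(transformed, meta, ped)
    fit, tests = compound_lmm.predictor_tests(data, predictors, seed=seed)
    lrt_rows = [
        {"model": name, "chi_sq": res.chi_sq, "df": res.df, "p": res.p}
        for name, res in tests
    ]
    slopes = compound_lmm.slope_table(fit)
    return CompositionResults(fit, pd.DataFrame(lrt_rows), slopes)
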