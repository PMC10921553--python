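"""End-to-end pipeline stages gluing the library modules together.

Each stage is a plain function over in-memory cohorts; the CLI wraps them
with file I/O.  The full study is: simulate paired phantoms -> preprocess ->
train one network per modality -> segment and score the held-out cases ->
extract radiomics from both modalities -> per-feature Pearson concordance.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .correlation import ConcordanceReport, correlate_tables
from .io import FeatureTable
from .model import build_network
from .preprocess import preprocess_case
from .radiomics import FeatureManifest, default_manifest, extract_features
from .synthetic import generate_cohort_arrays
from .train import evaluate_cohort, split_cohort, train

log = logging.getLogger("cbctomics")

__all__ = [
    "run_segmentation_study",
    "extract_cohort_features",
    "run_concordance_study",
]

_MOD_KEYS = {"PCT": ("pct", "pct_mask"), "CBCT": ("cbct", "cbct_mask")}


def _preprocessed(cases, cfg: RunConfig, modality: str):
    key, mkey = _MOD_KEYS[modality]
    prep = {}
    for c in cases:
        vp, mp, rec = preprocess_case(c[key], c[mkey], cfg.preprocess, return_record=True)
        prep[c["case_id"]] = {"vol": vp, "mask": mp, "record": rec, "ref_mask": c[mkey]}
    return prep


def run_segmentation_study(cfg: RunConfig, modality: str, cases=None):
    """Generate (or reuse) a cohort, train one modality, score the held-out split.

    Returns ``(network, history, per-case metrics table, summary)``.
    """
    if cases is None:
        cases = generate_cohort_arrays(cfg.cohort_size, cfg.phantom)
    prep = _preprocessed(cases, cfg, modality)
    ids = [c["case_id"] for c in cases]
    train_ids, test_ids = split_cohort(ids, cfg.training.train_fraction, cfg.seed)
    log.info("split: %d train / %d test", len(train_ids), len(test_ids))
    net = build_network(cfg.network, seed=cfg.seed)
    net, history = train(
        net,
        [(prep[i]["vol"], prep[i]["mask"]) for i in train_ids],
        cfg.training,
        loss_params=cfg.tversky,
    )
    table, summary = evaluate_cohort(
        net,
        [(prep[i]["vol"], prep[i]["ref_mask"]) for i in test_ids],
        case_ids=test_ids,
        records=[prep[i]["record"] for i in test_ids],
    )
    log.info("%s held-out mean DSC %.3f", modality, summary.loc["mean", "dsc"])
    return net, history, table, summary


def extract_cohort_features(
    cases,
    modality: str,
    manifest: FeatureManifest | None = None,
    masks: dict | None = None,
) -> FeatureTable:
    """Radiomic feature table for one modality of a paired cohort.

    ``masks`` may override the ground-truth masks (e.g. with network
    segmentations keyed by case id).
    """
    if manifest is None:
        manifest = default_manifest()
    key, mkey = _MOD_KEYS[modality]
    rows = {}
    for c in cases:
        m = masks[c["case_id"]] if masks is not None else c[mkey]
        rows[c["case_id"]] = extract_features(c[key], m, manifest)
    return FeatureTable.from_rows(rows)


def run_concordance_study(
    cfg: RunConfig,
    cases=None,
    manifest: FeatureManifest | None = None,
) -> ConcordanceReport:
    """Paired pCT/CBCT extraction + per-feature Pearson concordance."""
    if cases is None:
        cases = generate_cohort_arrays(cfg.cohort_size, cfg.phantom)
    t_pct = extract_cohort_features(cases, "PCT", manifest)
    t_cbct = extract_cohort_features(cases, "CBCT", manifest)
    report = correlate_tables(t_pct, t_cbct, threshold=cfg.correlation_threshold)
    log.info(
        "concordance: %d/%d features with R > %.2f",
        len(report.interchangeable),
        len(report.table),
        cfg.correlation_threshold,
    )
    return report
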