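"""Seeded synthetic two-tissue microarray data with known ground truth.

The generator emulates a paired two-tissue expression study: the same
subjects contribute a heart and a peripheral-blood (PBMC) array, a minority
of probes measure genuinely expressed transcripts while the rest sit at
background level, and treatment shifts a large, predominantly down-regulated
fraction of the expressed genes.  Gene-wise residual variances follow an
inverse-gamma-type prior (precision ``1/sigma^2 ~ Gamma(shape a, scale b)``),
the same family the moderated t-test downstream assumes, so parameter
recovery and false-discovery behaviour of the full pipeline can be measured
against an exact truth.

Every draw derives from a master seed through named, per-(tissue, stage)
child streams, so regeneration is bit-identical and enlarging one stage does
not perturb another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocess import IntensityMatrix

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_dataset",
    "generate_go_annotations",
    "generate_ct_table",
]

# Measurement share of the per-gene array variance: duplicate arrays of one
# subject re-draw only this component, the biological share is subject-level.
MEASUREMENT_VARIANCE_SHARE = 0.05

# Log2 offset of a gene's secondary probe relative to its primary probe.
SECONDARY_PROBE_OFFSET = -0.5

TISSUES = ("heart", "pbmc")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic two-tissue study.

    Defaults mirror the study design the package targets: ~22.5k probes of
    which ~40% are expressed, 8 control vs 9 treated subjects assayed in both
    tissues, 7 subjects with duplicate arrays, ~80% of expressed genes
    affected by treatment with ~90% of effects negative, and gene precisions
    drawn from a Gamma(a, scale=b) prior.
    """

    n_probes: int = 22523
    frac_expressed: float = 0.406
    n_control: int = 8
    n_treated: int = 9
    n_duplicate_arrays: int = 7
    affected_fraction: float = 0.8
    shared_fraction: float = 0.6
    down_fraction: float = 0.9
    effect_size_log2: tuple[float, float] = (1.5, 0.5)  # (mean, sd) of |effect|
    variance_prior_a: float = 2.0
    variance_prior_b: float = 10.0
    expressed_mean_range: tuple[float, float] = (8.0, 12.0)
    background_mean: float = 5.0
    background_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        checks = [
            (0.0 < self.frac_expressed < 1.0,
             f"frac_expressed must be in (0, 1), got {self.frac_expressed}"),
            (0.0 <= self.affected_fraction <= 1.0,
             f"affected_fraction must be in [0, 1], got {self.affected_fraction}"),
            (0.0 <= self.shared_fraction <= 1.0,
             f"shared_fraction must be in [0, 1], got {self.shared_fraction}"),
            (0.0 <= self.down_fraction <= 1.0,
             f"down_fraction must be in [0, 1], got {self.down_fraction}"),
            (self.variance_prior_a > 0,
             f"variance_prior_a must be > 0, got {self.variance_prior_a}"),
            (self.variance_prior_b > 0,
             f"variance_prior_b must be > 0, got {self.variance_prior_b}"),
            (self.n_control >= 2, f"n_control must be >= 2, got {self.n_control}"),
            (self.n_treated >= 2, f"n_treated must be >= 2, got {self.n_treated}"),
            (self.n_probes >= 10, f"n_probes must be >= 10, got {self.n_probes}"),
            (self.n_duplicate_arrays <= self.n_control + self.n_treated,
             "n_duplicate_arrays cannot exceed the number of subjects"),
            (self.background_sd > 0,
             f"background_sd must be > 0, got {self.background_sd}"),
            (self.expressed_mean_range[0] < self.expressed_mean_range[1],
             "expressed_mean_range must be an increasing interval"),
            (self.effect_size_log2[1] >= 0,
             "effect size sd must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(msg)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset.

    ``table`` holds one row per (expressed gene, tissue) with the affected
    flag, the signed true log2 effect and the true residual variance;
    ``probe_info`` records per probe whether it was generated as expressed and
    which gene it maps to (NaN for unmapped probes).
    """

    table: pd.DataFrame          # gene, tissue, affected, effect_log2, sigma2
    probe_info: pd.DataFrame     # probe_id, gene_symbol, expressed_true
    config: SimConfig = field(repr=False, default=None)

    def affected_genes(self, tissue: str) -> set[str]:
        t = self.table
        sel = t[(t["tissue"] == tissue) & t["affected"]]
        return set(sel["gene"])

    def expressed_genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["design"]
    for tissue in TISSUES:
        for stage in ("means", "variances", "effects", "noise", "background"):
            names.append(f"{tissue}/{stage}")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _subject_frame(config: SimConfig) -> pd.DataFrame:
    n = config.n_control + config.n_treated
    subjects = [f"s{j + 1:02d}" for j in range(n)]
    groups = ["control"] * config.n_control + ["treated"] * config.n_treated
    return pd.DataFrame({"subject_id": subjects, "group": groups})


def generate_dataset(
    config: SimConfig,
) -> tuple[IntensityMatrix, IntensityMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate paired heart and PBMC intensity matrices plus ground truth.

    Returns ``(heart, pbmc, probe_map, truth)`` where ``probe_map`` is a
    two-column frame (``probe_id``, ``gene_symbol``) covering the mapped
    subset of probes.  Intensities are strictly positive (raw scale,
    ``2**log2``); the same subject ids appear in both tissues; duplicate
    arrays re-draw only measurement noise for the flagged subjects.
    """
    rngs = _streams(config.seed)
    design = rngs["design"]

    # --- probe design (shared by both tissues) ---------------------------
    probe_ids = np.array([f"PR{i:06d}" for i in range(config.n_probes)])
    expressed_mask = design.random(config.n_probes) < config.frac_expressed
    expr_idx = np.flatnonzero(expressed_mask)
    null_idx = np.flatnonzero(~expressed_mask)
    m_expr = expr_idx.size
    if m_expr == 0 or null_idx.size == 0:
        raise ValidationError(
            "generated design has an empty expressed or background class; "
            "increase n_probes or adjust frac_expressed"
        )

    # Each expressed probe starts as the unique probe of its own gene; a few
    # probes are then re-assigned to another expressed gene so that some
    # genes carry two probes (exercising probe collapse downstream).
    gene_of_expr_probe = np.arange(m_expr)
    probe_offset = np.zeros(m_expr)
    n_dup_probes = int(round(0.03 * m_expr))
    if n_dup_probes > 0 and m_expr > 1:
        dup_probes = design.choice(m_expr, size=n_dup_probes, replace=False)
        hosts = design.integers(0, m_expr, size=n_dup_probes)
        hosts = np.where(hosts == dup_probes, (hosts + 1) % m_expr, hosts)
        gene_of_expr_probe[dup_probes] = gene_of_expr_probe[hosts]
        probe_offset[dup_probes] = SECONDARY_PROBE_OFFSET

    live_genes = np.unique(gene_of_expr_probe)
    gene_symbols = {g: f"GENE{g:05d}" for g in live_genes}

    # Background probes: 90% map to never-expressed gene symbols, the rest
    # have no known gene and are dropped at probe collapse.
    bg_mapped_mask = design.random(null_idx.size) < 0.9
    bg_symbols = np.array(
        [f"GENEU{i:05d}" for i in range(int(bg_mapped_mask.sum()))]
    )

    map_probes = list(probe_ids[expr_idx])
    map_genes = [gene_symbols[g] for g in gene_of_expr_probe]
    map_probes += list(probe_ids[null_idx[bg_mapped_mask]])
    map_genes += list(bg_symbols)
    probe_map = pd.DataFrame({"probe_id": map_probes, "gene_symbol": map_genes})

    # --- treatment effects -----------------------------------------------
    subjects = _subject_frame(config)
    n_subjects = len(subjects)
    treated_mask = (subjects["group"] == "treated").to_numpy()

    n_genes = live_genes.size
    mu, sd = config.effect_size_log2

    # A gene is "shared affected" (same signed effect in both tissues) with
    # probability affected_fraction * shared_fraction, and independently
    # tissue-specific affected with the complementary share, so the marginal
    # affected fraction per tissue equals affected_fraction.
    p_shared = config.affected_fraction * config.shared_fraction
    p_specific = config.affected_fraction * (1.0 - config.shared_fraction)
    u = design.random(n_genes)
    shared_affected = u < p_shared
    shared_mag = np.abs(design.normal(mu, sd, size=n_genes))
    shared_sign = np.where(design.random(n_genes) < config.down_fraction, -1.0, 1.0)
    shared_effect = np.where(shared_affected, shared_sign * shared_mag, 0.0)

    effects: dict[str, np.ndarray] = {}
    affected: dict[str, np.ndarray] = {}
    for tissue in TISSUES:
        rng = rngs[f"{tissue}/effects"]
        specific = (~shared_affected) & (rng.random(n_genes) < (
            p_specific / max(1.0 - p_shared, 1e-12)))
        mag = np.abs(rng.normal(mu, sd, size=n_genes))
        sign = np.where(rng.random(n_genes) < config.down_fraction, -1.0, 1.0)
        eff = shared_effect.copy()
        eff[specific] = (sign * mag)[specific]
        affected[tissue] = shared_affected | specific
        effects[tissue] = eff

    # --- per-tissue matrices ---------------------------------------------
    dup_subject_idx = (
        design.choice(n_subjects, size=config.n_duplicate_arrays, replace=False)
        if config.n_duplicate_arrays > 0
        else np.array([], dtype=int)
    )

    truth_rows = []
    matrices: dict[str, IntensityMatrix] = {}
    rho = MEASUREMENT_VARIANCE_SHARE
    for tissue in TISSUES:
        base_mean = rngs[f"{tissue}/means"].uniform(
            *config.expressed_mean_range, size=n_genes
        )
        precision = rngs[f"{tissue}/variances"].gamma(
            config.variance_prior_a, config.variance_prior_b, size=n_genes
        )
        sigma2 = 1.0 / precision

        noise_rng = rngs[f"{tissue}/noise"]
        # Subject-level expression: baseline + effect (treated) + biological noise.
        gene_mean = base_mean[:, None] + np.where(
            treated_mask[None, :], effects[tissue][:, None], 0.0
        )
        bio_sd = np.sqrt(sigma2 * (1.0 - rho))
        subject_expr = gene_mean + noise_rng.normal(size=(n_genes, n_subjects)) * bio_sd[:, None]

        # Array layer: primary array per subject, plus duplicates; each array
        # re-draws the measurement component only.
        array_cols = []   # (sample_id, subject_row, replicate)
        for j in range(n_subjects):
            array_cols.append((j, 1))
        for j in dup_subject_idx:
            array_cols.append((int(j), 2))

        meas_sd = np.sqrt(sigma2 * rho)
        n_arrays = len(array_cols)
        log2 = np.empty((config.n_probes, n_arrays))

        gene_row_of_probe = np.searchsorted(live_genes, gene_of_expr_probe)
        for k, (j, _rep) in enumerate(array_cols):
            probe_signal = (
                subject_expr[gene_row_of_probe, j]
                + probe_offset
                + noise_rng.normal(size=m_expr) * meas_sd[gene_row_of_probe]
            )
            log2[expr_idx, k] = probe_signal
        bg_rng = rngs[f"{tissue}/background"]
        log2[null_idx, :] = bg_rng.normal(
            config.background_mean, config.background_sd,
            size=(null_idx.size, n_arrays),
        )

        sample_ids = [
            f"{tissue}_{subjects['subject_id'][j]}_r{rep}" for j, rep in array_cols
        ]
        metadata = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "subject_id": [subjects["subject_id"][j] for j, _ in array_cols],
                "tissue": tissue,
                "group": [subjects["group"][j] for j, _ in array_cols],
                "replicate": [rep for _, rep in array_cols],
            }
        ).set_index("sample_id")
        values = pd.DataFrame(
            np.exp2(log2), index=pd.Index(probe_ids, name="probe_id"),
            columns=sample_ids,
        )
        matrices[tissue] = IntensityMatrix(values=values, metadata=metadata)

        for row, g in enumerate(live_genes):
            truth_rows.append(
                (
                    gene_symbols[g],
                    tissue,
                    bool(affected[tissue][row]),
                    float(effects[tissue][row]),
                    float(sigma2[row]),
                )
            )

    truth = SyntheticTruth(
        table=pd.DataFrame(
            truth_rows, columns=["gene", "tissue", "affected", "effect_log2", "sigma2"]
        ),
        probe_info=pd.DataFrame(
            {
                "probe_id": probe_ids,
                "gene_symbol": pd.Series(
                    dict(zip(probe_map["probe_id"], probe_map["gene_symbol"]))
                ).reindex(probe_ids).to_numpy(),
                "expressed_true": expressed_mask,
            }
        ),
        config=config,
    )
    return matrices["heart"], matrices["pbmc"], probe_map, truth


def generate_go_annotations(
    gene_ids: Sequence[str],
    n_terms: int,
    term_size_range: tuple[int, int],
    enriched_terms: int,
    seed: int,
    affected_genes: Sequence[str] = (),
    affected_member_fraction: float = 0.8,
) -> tuple[pd.DataFrame, list[str]]:
    """Random GO-style annotations with a known enriched subset of terms.

    Returns an annotation table (``term_id, aspect, gene_symbol``) and the
    list of truly enriched term ids.  Enriched terms draw
    ``affected_member_fraction`` of their members from ``affected_genes``;
    all other terms are uniform random gene subsets.  Serializable as GAF
    via :func:`twotissue.io.write_gaf`.
    """
    genes = list(gene_ids)
    if not genes:
        raise ValidationError("gene_ids must be non-empty")
    lo, hi = term_size_range
    if lo < 1 or hi > len(genes) or lo > hi:
        raise ValidationError(
            f"term_size_range {term_size_range} must lie within [1, {len(genes)}]"
        )
    if enriched_terms > n_terms:
        raise ValidationError("enriched_terms cannot exceed n_terms")
    affected = [g for g in affected_genes if g in set(genes)]
    if enriched_terms > 0 and not affected:
        raise ValidationError("enriched terms requested but no affected genes given")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x60]))
    aspects = np.array(["biological_process", "molecular_function", "cellular_component"])
    others = sorted(set(genes) - set(affected))
    rows = []
    enriched_ids = []
    for t in range(n_terms):
        term_id = f"GO:{t + 1:07d}"
        size = int(rng.integers(lo, hi + 1))
        aspect = str(rng.choice(aspects))
        if t < enriched_terms:
            n_aff = min(int(round(affected_member_fraction * size)), len(affected))
            members = list(rng.choice(affected, size=n_aff, replace=False))
            pool = others if others else affected
            rest = size - n_aff
            if rest > 0:
                members += list(rng.choice(pool, size=min(rest, len(pool)), replace=False))
            enriched_ids.append(term_id)
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        for g in dict.fromkeys(members):
            rows.append((term_id, aspect, g))
    table = pd.DataFrame(rows, columns=["term_id", "aspect", "gene_symbol"])
    return table, enriched_ids


def generate_ct_table(
    truth: SyntheticTruth,
    genes: Sequence[str],
    n_replicates: int = 3,
    housekeeping_ct: float = 15.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    tissue: str = "heart",
    housekeeping_gene: str = "18S",
) -> pd.DataFrame:
    """qPCR threshold-cycle table consistent with the synthetic truth.

    Each gene's treated-vs-control mean delta-Ct equals minus its true log2
    effect (plus noise), so the 2^-ddCt method recovers ``2**effect``.
    Housekeeping rows are present for every sample.  Columns:
    ``sample_id, group, gene, replicate, ct``.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    known = set(truth.table.loc[truth.table["tissue"] == tissue, "gene"])
    unknown = [g for g in genes if g not in known]
    if unknown:
        raise ValidationError(f"genes not present in truth for {tissue}: {unknown}")

    cfg = truth.config
    tt = truth.table[truth.table["tissue"] == tissue].set_index("gene")
    subjects = _subject_frame(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC7]))

    rows = []
    baselines = {g: float(rng.uniform(22.0, 28.0)) for g in genes}
    for _, subj in subjects.iterrows():
        sample = f"{tissue}_{subj['subject_id']}"
        treated = subj["group"] == "treated"
        for rep in range(1, n_replicates + 1):
            rows.append(
                (sample, subj["group"], housekeeping_gene, rep,
                 housekeeping_ct + rng.normal(0.0, noise_sd) if noise_sd > 0 else housekeeping_ct)
            )
        for g in genes:
            # higher expression -> fewer cycles to threshold
            ct0 = baselines[g] - (tt.loc[g, "effect_log2"] if treated else 0.0)
            for rep in range(1, n_replicates + 1):
                ct = ct0 + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append((sample, subj["group"], g, rep, ct))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "replicate", "ct"])
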