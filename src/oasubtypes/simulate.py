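"""Synthetic multi-tissue OA cohort generator with known ground truth.

Emulates the structure of a multi-center knee-osteoarthritis BRB-seq style
cohort: cartilage counts for every patient (plus a handful of non-OA
amputation controls), synovium and subchondral bone counts for a subset of
patients, four planted molecular subtypes at uneven proportions with
subtype-specific marker-gene blocks, planted directional ligand-receptor
co-expression between tissues, and ordered clinical scores (KL, osteophyte,
JSN, age) whose distributions shift with subtype.

Counts are negative-binomial with log-normal gene base means scaled to a
per-sample target library size, so simulated totals land inside (or, when
configured wider, outside) the sequencing-depth QC window downstream.
All randomness flows from ``CohortConfig.seed``; the same config yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .io import TISSUES, ValidationError

SUBTYPES = ("C1", "C2", "C3", "C4")

# Abundance model: gene base means are log-normal(meanlog 3, sdlog 1.2),
# giving heavy-tailed bulk-RNA-seq-like CPM distributions.
BASE_MEANLOG = 3.0
BASE_SDLOG = 1.2

# Planted ligand/receptor genes sit at a low baseline (CPM << 1) and are
# boosted 64x in the planted (tissue, subtype) so the co-expression rule
# fires only for the planted direction.
CROSSTALK_BASE_MEAN = 0.05
CROSSTALK_BOOST = 64.0

# Controls are drawn at a quarter of the OA dispersion: amputation cartilage
# without OA is transcriptionally quieter than end-stage disease tissue.
CONTROL_DISPERSION_FACTOR = 0.25

# Per-subtype clinical generative parameters (C2: severe osteophytes,
# C4: narrow joint space, C3: younger patients), scaled by
# ``clinical_effect_scale`` so the null (no-effect) cohort is one knob away.
OSTEO_P_BASE, OSTEO_P_DELTA = 0.35, (0.0, 0.27, 0.0, 0.05)
JSN_Q_BASE, JSN_Q_DELTA = 0.35, (0.0, 0.05, 0.0, 0.33)
AGE_MEAN_BASE, AGE_MEAN_DELTA = 68.0, (0.0, 1.0, -10.0, -1.0)
AGE_SD = 6.0


@dataclass
class CohortConfig:
    """Parameters of the synthetic multi-tissue cohort."""

    n_patients: int = 131
    subtype_proportions: tuple[float, ...] = (0.618, 0.183, 0.076, 0.122)
    n_genes: int = 6000
    n_markers_per_subtype: int = 60
    marker_log2fc: float = 2.0
    nb_dispersion: float = 0.2
    library_size_range: tuple[int, int] = (600_000, 1_800_000)
    n_controls: int = 4
    tissue_missing_rate: float = 0.5
    n_lr_pairs: int = 300
    n_planted_crosstalk_per_subtype: int = 20
    clinical_effect_scale: float = 1.0
    seed: int = 0
    # gene-level plan seed (marker blocks, crosstalk pairs, base means);
    # defaults to `seed`.  An external validation cohort drawn with a fresh
    # `seed` but the discovery run's `biology_seed` shares its planted
    # markers and crosstalk while resampling patients and counts.
    biology_seed: int | None = None

    def __post_init__(self):
        def bad(name, why):
            raise ValidationError(f"CohortConfig.{name}: {why}")

        for name in ("n_patients", "n_genes", "n_markers_per_subtype"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                bad(name, f"must be a positive integer, got {v!r}")
        for name in ("n_controls", "n_lr_pairs", "n_planted_crosstalk_per_subtype"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                bad(name, f"must be a non-negative integer, got {v!r}")
        props = tuple(float(p) for p in self.subtype_proportions)
        if len(props) != len(SUBTYPES) or any(p < 0 for p in props):
            bad("subtype_proportions", f"need {len(SUBTYPES)} non-negative reals")
        # printed cohort shares (61.8/18.3/7.6/12.2%) sum to 99.9% after
        # rounding, so tolerate sub-percent slack and renormalize
        if abs(sum(props) - 1.0) > 1e-2:
            bad("subtype_proportions", f"must sum to 1, got {sum(props)}")
        self.subtype_proportions = tuple(p / sum(props) for p in props)
        if self.marker_log2fc < 0:
            bad("marker_log2fc", "must be non-negative")
        if self.nb_dispersion <= 0:
            bad("nb_dispersion", "must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo < hi):
            bad("library_size_range", f"need 0 < low < high, got {(lo, hi)}")
        if not (0 <= self.tissue_missing_rate < 1):
            bad("tissue_missing_rate", "must be in [0, 1)")
        if self.n_lr_pairs > self.n_genes // 2:
            bad("n_lr_pairs", f"{self.n_lr_pairs} pairs exceed n_genes/2")
        needed = 4 * self.n_markers_per_subtype + 8 * self.n_planted_crosstalk_per_subtype
        if needed > self.n_genes:
            bad("n_genes", f"too small for {needed} marker+crosstalk genes")
        if self.n_planted_crosstalk_per_subtype * len(SUBTYPES) > self.n_lr_pairs:
            bad("n_lr_pairs", "fewer pairs than planted crosstalk pairs")
        if not isinstance(self.seed, (int, np.integer)):
            bad("seed", "must be an integer")
        if self.biology_seed is not None and not isinstance(
                self.biology_seed, (int, np.integer)):
            bad("biology_seed", "must be an integer or None")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for downstream recovery checks."""

    patient_subtype: dict[str, str]
    marker_genes: dict[str, list[str]]
    planted_crosstalk: list[tuple[str, str, str, str, str]]
    clinical_effects: dict[str, dict[str, float]]

    def to_json(self, path: str | Path) -> None:
        obj = asdict(self)
        obj["planted_crosstalk"] = [list(t) for t in self.planted_crosstalk]
        oio.write_json(obj, path)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        obj = oio.read_json(path)
        obj["planted_crosstalk"] = [tuple(t) for t in obj["planted_crosstalk"]]
        return cls(**obj)


def largest_remainder(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Apportion ``n`` items to groups by largest-remainder rounding.

    Deterministic: floors first, then hands the leftover units to the
    groups with the largest fractional remainders (ties by group order).
    """
    quotas = np.asarray(proportions, dtype=float) * n
    sizes = np.floor(quotas).astype(int)
    remainder = n - sizes.sum()
    # stable argsort on negated remainders -> ties broken by index order
    order = np.argsort(-(quotas - sizes), kind="stable")
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes.tolist()


def _plan(config: CohortConfig) -> dict:
    """Deterministic cohort plan shared by all generator entry points.

    Derives, from the seed alone, the gene universe, subtype assignment,
    marker blocks, planted crosstalk pairs, tissue availability and
    clinical parameters — so counts, LR table and gene sets generated in
    separate calls agree with one another.
    """
    bio_seed = config.seed if config.biology_seed is None else config.biology_seed
    rng_bio = np.random.default_rng(np.random.SeedSequence([int(bio_seed), 0xC047]))
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x5A11]))
    width = max(4, len(str(config.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]

    sizes = largest_remainder(config.n_patients, config.subtype_proportions)
    labels = np.repeat(SUBTYPES, sizes)
    labels = labels[rng.permutation(config.n_patients)]
    patients = [f"P{i:04d}" for i in range(1, config.n_patients + 1)]
    patient_subtype = dict(zip(patients, labels.tolist()))

    # disjoint marker blocks and crosstalk genes, drawn without replacement
    # from the biology rng so cohorts sharing biology_seed share them
    n_ct_genes = 8 * config.n_planted_crosstalk_per_subtype
    n_special = 4 * config.n_markers_per_subtype + n_ct_genes
    special = rng_bio.choice(config.n_genes, size=n_special, replace=False)
    marker_genes, pos = {}, 0
    for s in SUBTYPES:
        idx = special[pos:pos + config.n_markers_per_subtype]
        marker_genes[s] = sorted(genes[i] for i in idx)
        pos += config.n_markers_per_subtype
    ct_idx = special[pos:]

    planted = []
    k = config.n_planted_crosstalk_per_subtype
    directions = [("cartilage", "subchondral_bone"), ("synovium", "cartilage"),
                  ("subchondral_bone", "synovium"), ("cartilage", "synovium")]
    for si, s in enumerate(SUBTYPES):
        src, dst = directions[si % len(directions)]
        for j in range(k):
            lig = genes[ct_idx[2 * (si * k + j)]]
            rec = genes[ct_idx[2 * (si * k + j) + 1]]
            planted.append((lig, rec, src, dst, s))

    base_means = rng_bio.lognormal(BASE_MEANLOG, BASE_SDLOG, size=config.n_genes)
    base_means[ct_idx] = CROSSTALK_BASE_MEAN

    # tissue availability: cartilage always sampled; others Bernoulli per patient
    present = {"cartilage": np.ones(config.n_patients, dtype=bool)}
    for t in ("synovium", "subchondral_bone"):
        present[t] = rng.random(config.n_patients) >= config.tissue_missing_rate

    sc = config.clinical_effect_scale
    clinical_effects = {
        s: {
            "osteophyte_p": OSTEO_P_BASE + sc * OSTEO_P_DELTA[i],
            "jsn_q": JSN_Q_BASE + sc * JSN_Q_DELTA[i],
            "age_mean": AGE_MEAN_BASE + sc * AGE_MEAN_DELTA[i],
        }
        for i, s in enumerate(SUBTYPES)
    }

    return {
        "rng": rng, "genes": genes, "patients": patients,
        "patient_subtype": patient_subtype, "marker_genes": marker_genes,
        "planted": planted, "base_means": base_means, "present": present,
        "clinical_effects": clinical_effects, "ct_idx": ct_idx,
    }


def _draw_counts(rng, mean_matrix: np.ndarray, library_sizes: np.ndarray,
                 dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) counts with each column scaled to its target depth."""
    mu = mean_matrix / mean_matrix.sum(axis=0, keepdims=True) * library_sizes
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(np.int64)


def generate_cohort(config: CohortConfig):
    """Generate per-tissue count matrices, a sample table and the truth.

    Returns ``(counts, meta, truth)`` where ``counts`` maps tissue name to a
    genes×samples integer DataFrame, ``meta`` is the sample metadata table
    and ``truth`` records planted subtypes, markers, crosstalk and clinical
    effect parameters.
    """
    plan = _plan(config)
    rng = plan["rng"]
    genes, patients = plan["genes"], plan["patients"]
    gene_pos = {g: i for i, g in enumerate(genes)}
    subtype_of = plan["patient_subtype"]
    marker_fc = 2.0 ** config.marker_log2fc
    lo, hi = config.library_size_range

    counts: dict[str, pd.DataFrame] = {}
    meta_rows: list[dict] = []

    # clinical scores per patient (independent of tissue)
    eff = plan["clinical_effects"]
    clin: dict[str, dict] = {}
    for p in patients:
        e = eff[subtype_of[p]]
        clin[p] = {
            "age": int(np.clip(round(rng.normal(e["age_mean"], AGE_SD)), 40, 90)),
            "sex": "F" if rng.random() < 0.55 else "M",
            "kl": 3 + int(rng.random() < 0.5),
            "osteophyte": int(rng.binomial(12, min(max(e["osteophyte_p"], 0.0), 1.0))),
            "jsn": int(rng.binomial(6, min(max(e["jsn_q"], 0.0), 1.0))),
            "center": f"center{1 + int(rng.integers(4))}",
        }

    for tissue in TISSUES:
        keep = plan["present"][tissue]
        tissue_patients = [p for p, k in zip(patients, keep) if k]
        cols = []
        mean_cols = []
        for p in tissue_patients:
            m = plan["base_means"].copy()
            s = subtype_of[p]
            if tissue == "cartilage" and marker_fc != 1.0:
                idx = [gene_pos[g] for g in plan["marker_genes"][s]]
                m[idx] *= marker_fc
            for lig, rec, src, dst, ps in plan["planted"]:
                if ps != s:
                    continue
                if src == tissue:
                    m[gene_pos[lig]] *= CROSSTALK_BOOST
                if dst == tissue:
                    m[gene_pos[rec]] *= CROSSTALK_BOOST
            mean_cols.append(m)
            sid = f"{p}_{tissue}"
            cols.append(sid)
            row = {"sample_id": sid, "patient_id": p, "tissue": tissue,
                   "status": "OA", **clin[p]}
            meta_rows.append(row)
        if tissue == "cartilage":
            for c in range(1, config.n_controls + 1):
                pid = f"CTRL{c:02d}"
                sid = f"{pid}_{tissue}"
                mean_cols.append(plan["base_means"].copy())
                cols.append(sid)
                meta_rows.append({
                    "sample_id": sid, "patient_id": pid, "tissue": tissue,
                    "status": "control",
                    "age": int(np.clip(round(rng.normal(45, 8)), 18, 80)),
                    "sex": "F" if rng.random() < 0.5 else "M",
                    "center": "center1",
                    "kl": pd.NA, "osteophyte": pd.NA, "jsn": pd.NA,
                })
        mean_matrix = np.column_stack(mean_cols)
        libs = rng.integers(lo, hi + 1, size=len(cols)).astype(float)
        n_ctrl = config.n_controls if tissue == "cartilage" else 0
        n_oa = len(cols) - n_ctrl
        oa_counts = _draw_counts(rng, mean_matrix[:, :n_oa], libs[:n_oa],
                                 config.nb_dispersion)
        blocks = [oa_counts]
        if n_ctrl:
            ctrl_counts = _draw_counts(
                rng, mean_matrix[:, n_oa:], libs[n_oa:],
                config.nb_dispersion * CONTROL_DISPERSION_FACTOR)
            blocks.append(ctrl_counts)
        counts[tissue] = pd.DataFrame(np.hstack(blocks), index=genes, columns=cols)

    meta = pd.DataFrame(meta_rows, columns=list(oio.SAMPLE_TABLE_COLUMNS))
    meta = oio.validate_sample_table(meta)
    truth = SyntheticTruth(
        patient_subtype=plan["patient_subtype"],
        marker_genes=plan["marker_genes"],
        planted_crosstalk=plan["planted"],
        clinical_effects=plan["clinical_effects"],
    )
    return counts, meta, truth


def generate_lr_database(config: CohortConfig) -> pd.DataFrame:
    """Two-column ligand-receptor table containing every planted pair plus
    random filler pairs over the remaining gene universe."""
    plan = _plan(config)
    bio_seed = config.seed if config.biology_seed is None else config.biology_seed
    rng = np.random.default_rng(np.random.SeedSequence([int(bio_seed), 0x1BDB]))
    rows = [(lig, rec) for lig, rec, *_ in plan["planted"]]
    used = {g for pair in rows for g in pair}
    pool = [g for g in plan["genes"] if g not in used]
    n_fill = config.n_lr_pairs - len(rows)
    if n_fill > 0:
        picks = rng.choice(len(pool), size=2 * n_fill, replace=False)
        for j in range(n_fill):
            rows.append((pool[picks[2 * j]], pool[picks[2 * j + 1]]))
    df = pd.DataFrame(rows, columns=["ligand", "receptor"])
    assert not df.duplicated().any()
    return df


def generate_genesets(config: CohortConfig, n_random_sets: int = 6,
                      random_set_size: int = 30) -> dict[str, list[str]]:
    """GMT-style gene sets: one positive-control set per subtype containing
    that subtype's planted crosstalk genes, plus random background sets."""
    plan = _plan(config)
    bio_seed = config.seed if config.biology_seed is None else config.biology_seed
    rng = np.random.default_rng(np.random.SeedSequence([int(bio_seed), 0x6E75]))
    sets: dict[str, list[str]] = {}
    for s in SUBTYPES:
        members = sorted({g for lig, rec, _, _, ps in plan["planted"] if ps == s
                          for g in (lig, rec)})
        while len(members) < 10:  # keep positive controls at a usable size
            extra = plan["genes"][int(rng.integers(config.n_genes))]
            if extra not in members:
                members.append(extra)
        sets[f"positive_control_{s}"] = members
    for j in range(1, n_random_sets + 1):
        idx = rng.choice(config.n_genes, size=random_set_size, replace=False)
        sets[f"random_set_{j}"] = sorted(plan["genes"][i] for i in idx)
    return sets


def write_cohort(config: CohortConfig, outdir: str | Path,
                 format: str = "tsv") -> None:
    """Generate a cohort and write every table to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, meta, truth = generate_cohort(config)
    for tissue, df in counts.items():
        ext = "mtx" if format == "mtx" else "tsv"
        oio.write_count_matrix(df, outdir / f"counts_{tissue}.{ext}", format=format)
    oio.write_sample_table(meta, outdir / "samples.tsv")
    oio.write_lr_table(generate_lr_database(config), outdir / "lr_pairs.tsv")
    oio.write_gmt(generate_genesets(config), outdir / "genesets.gmt")
    truth.to_json(outdir / "truth.json")
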