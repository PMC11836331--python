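"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is a pure function of its configuration, including the seed:
the same config yields bit-identical output.  Per-gene / per-ROI sub-streams
are derived from the seed with ``numpy.random.SeedSequence`` spawn keys, so
enlarging a fixture (more ROIs, more genes) does not perturb the parts that
already existed.

The expression generator emulates the structure of a multi-condition PSC
culture study: culture-condition groups (UD/FD/T) plus optional fibroblast
outgroup, technical replicates nested in biological samples, genetically
identical duplicate donors (clones/twins), sex and disease covariates, and a
planted set of differentially expressed genes with a known log2 fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calcium import TraceSet
from .network import CATEGORIES, InteractionNetwork, assemble_network

__all__ = [
    "SimConfig",
    "NetSimConfig",
    "TraceSimConfig",
    "gen_expression_study",
    "gen_reference_network",
    "gen_annotation_db",
    "gen_traces",
    "gen_ct_table",
    "write_study",
]

_GROUPS = ("UD", "FD", "T", "FIB")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class SimConfig:
    """Design of a synthetic expression study.

    Differential expression is planted between the first two groups in
    ``groups``: the chosen DE genes get a log2 shift of ``de_log2fc`` in the
    second group (half up, half down).  ``donor_sd`` controls the shared
    log2 shift of samples from the same donor (clones / monozygotic twins);
    the study it emulates does not pin this quantity down, so it is a free
    parameter defaulting to 0.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 8
    groups: Sequence[str] = ("UD", "FD")
    n_de_genes: int = 100
    de_log2fc: float = 2.0
    noise_sd: float = 1.0
    covariates: bool = True
    n_tech_reps: int = 1
    duplicate_donors: int = 0
    donor_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_group < 1 or self.n_tech_reps < 1:
            raise ValueError("counts must be >= 1")
        if self.n_de_genes < 0:
            raise ValueError("n_de_genes must be >= 0")
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        for g in self.groups:
            if g not in _GROUPS:
                raise ValueError(f"unknown group label {g!r}")
        if not np.isfinite(self.de_log2fc):
            raise ValueError("de_log2fc must be finite")
        if self.noise_sd < 0 or self.donor_sd < 0:
            raise ValueError("noise/donor SDs must be >= 0")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes exceeds n_genes")
        if self.duplicate_donors * 2 > self.n_samples_per_group:
            raise ValueError("too many duplicate donor pairs for the group size")


def gen_expression_study(cfg: SimConfig):
    """Generate (expression matrix, sample sheet, truth table of DE genes).

    Matrix: ``n_genes`` rows × (groups × n_samples_per_group × n_tech_reps)
    columns of log2 intensities.  Technical replicates share a
    ``tech_rep_group`` id; within each group the first ``duplicate_donors``
    pairs of biological samples share a donor id and a twin id.  The truth
    table lists each planted DE gene with its signed log2 fold change
    (group2 − group1); the group-mean difference equals it exactly when
    ``noise_sd`` is 0.
    """
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    rng_struct = _rng(cfg.seed, 0)
    baseline = rng_struct.normal(8.0, 1.5, size=cfg.n_genes)

    de_idx = rng_struct.choice(cfg.n_genes, size=cfg.n_de_genes, replace=False)
    de_idx.sort()
    signs = np.ones(cfg.n_de_genes)
    signs[1::2] = -1.0  # half up, half down, deterministically interleaved
    effects = np.zeros(cfg.n_genes)
    effects[de_idx] = signs * cfg.de_log2fc

    rows_meta = []
    columns: dict[str, np.ndarray] = {}
    g1, g2 = cfg.groups[0], cfg.groups[1]
    donor_counter = 0
    for gi, group in enumerate(cfg.groups):
        # donor assignment: duplicate pairs share a donor, rest unique
        donors = []
        twins = []
        for si in range(cfg.n_samples_per_group):
            if si < 2 * cfg.duplicate_donors:
                pair = si // 2
                donors.append(f"D{donor_counter + pair:03d}")
                twins.append(f"TW{donor_counter + pair:03d}")
            else:
                donors.append(f"D{donor_counter + cfg.duplicate_donors + si:03d}")
                twins.append("none")
        donor_counter += cfg.duplicate_donors + cfg.n_samples_per_group

        group_effect = effects if group == g2 else np.zeros(cfg.n_genes)
        for si in range(cfg.n_samples_per_group):
            srng = _rng(cfg.seed, 1, gi, si)
            donor_shift = (
                srng.normal(0.0, cfg.donor_sd, size=cfg.n_genes)
                if cfg.donor_sd > 0 else 0.0
            )
            bio_mean = baseline + group_effect + donor_shift
            sample_id = f"{group}_S{si:02d}"
            sex = str(srng.choice(["F", "M"])) if cfg.covariates else "F"
            disease = str(srng.choice(["healthy", "disease"])) if cfg.covariates else "healthy"
            cell_type = "fibroblast" if group == "FIB" else str(
                srng.choice(["iPSC", "ESC"], p=[0.8, 0.2])
            )
            passage = int(srng.integers(10, 40))
            for ti in range(cfg.n_tech_reps):
                col = f"{sample_id}_r{ti}"
                noise = (
                    srng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
                    if cfg.noise_sd > 0 else 0.0
                )
                columns[col] = bio_mean + noise
                rows_meta.append({
                    "sample": col,
                    "group": group,
                    "cell_type": cell_type,
                    "donor": donors[si],
                    "sex": sex,
                    "disease": disease,
                    "twin": twins[si],
                    "tech_rep_group": sample_id,
                    "passage": passage,
                })
    matrix = pd.DataFrame(columns, index=genes)
    samples = pd.DataFrame(rows_meta).set_index("sample")
    samples.index.name = None
    truth = pd.DataFrame({
        "gene": [genes[i] for i in de_idx],
        "log2fc": effects[de_idx],
        "direction": np.where(effects[de_idx] >= 0, "up", "down"),
        "comparison": f"{g2}_vs_{g1}",
    })
    return matrix, samples, truth


@dataclass
class NetSimConfig:
    """Erdős–Rényi multi-category background with a planted dense subset."""

    n_nodes: int = 200
    background_edge_prob: float = 0.02
    categories: Sequence[str] = ("physical",)
    planted_set_size: int = 0
    planted_edge_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        for p in (self.background_edge_prob, self.planted_edge_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("edge probabilities must lie in [0, 1]")
        for c in self.categories:
            if c not in CATEGORIES:
                raise ValueError(f"unknown interaction category {c!r}")
        if self.planted_set_size > self.n_nodes:
            raise ValueError("planted_set_size exceeds n_nodes")


def gen_reference_network(cfg: NetSimConfig):
    """Generate (InteractionNetwork, planted node list).

    Per category, each node pair gets a background edge independently with
    ``background_edge_prob``.  Within the planted set, the edge probability
    of the first category is ``planted_edge_prob`` instead of the background
    value, so planted == background is a true null and planted = 1 with
    background = 0 yields exactly one clique.  All nodes are present in the
    network even when isolated.
    """
    nodes = [f"N{i:04d}" for i in range(cfg.n_nodes)]
    rng = _rng(cfg.seed, 0)
    planted = sorted(rng.choice(cfg.n_nodes, size=cfg.planted_set_size, replace=False))
    planted_nodes = [nodes[i] for i in planted]
    iu, ju = np.triu_indices(cfg.n_nodes, k=1)
    pset = set(planted)
    in_planted = np.array(
        [a in pset and b in pset for a, b in zip(iu, ju)], dtype=bool
    ) if cfg.planted_set_size >= 2 else np.zeros(len(iu), dtype=bool)
    edge_lists: dict[str, list[tuple[str, str]]] = {}
    for ci, cat in enumerate(cfg.categories):
        crng = _rng(cfg.seed, 1, ci)
        draws = crng.random(len(iu))
        prob = np.full(len(iu), cfg.background_edge_prob)
        if ci == 0:
            prob[in_planted] = cfg.planted_edge_prob
        mask = draws < prob
        edge_lists[cat] = [(nodes[a], nodes[b]) for a, b in zip(iu[mask], ju[mask])]
    net = assemble_network(edge_lists)
    net.graph.add_nodes_from(nodes)  # keep isolated nodes in the universe
    return net, planted_nodes


def gen_annotation_db(
    n_terms: int,
    term_size_range: tuple[int, int],
    universe: Sequence[str],
    planted: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
):
    """Random annotation term sets over a universe, plus exact planted terms."""
    from .enrich import AnnotationDB

    universe = [str(g).strip().upper() for g in universe]
    if not universe:
        raise ValueError("universe must be nonempty")
    lo, hi = term_size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError("invalid term size range for this universe")
    rng = _rng(seed, 0)
    terms: dict[str, frozenset] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        terms[f"TERM{i:04d}"] = frozenset(universe[j] for j in members)
    uni_set = set(universe)
    for term, genes in (planted or {}).items():
        gs = frozenset(str(g).strip().upper() for g in genes)
        if not gs <= uni_set:
            raise ValueError(f"planted term {term!r} has genes outside the universe")
        terms[term] = gs
    return AnnotationDB(terms=terms)


@dataclass
class TraceSimConfig:
    """Ca2+ fluorescence trace simulation: Poisson-timed transient kernels.

    Each transient is a linear rise to ``amplitude_dff`` over ``rise_s``
    followed by exponential decay with time constant ``decay_s``, on top of
    Gaussian noise.  With ``stimulus_time_s`` set, a ``responder_fraction``
    of ROIs receives one large stimulus-locked event of amplitude
    ``stim_amplitude_dff``.
    """

    duration_s: float = 900.0
    sampling_hz: float = 0.5
    n_rois: int = 50
    event_rate_hz: float = 0.01
    amplitude_dff: float = 0.8
    rise_s: float = 4.0
    decay_s: float = 10.0
    noise_sd: float = 0.02
    stimulus_time_s: float | None = None
    responder_fraction: float = 0.3
    stim_amplitude_dff: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sampling_hz and duration_s must be positive")
        if self.amplitude_dff <= 0:
            raise ValueError("amplitude_dff must be positive")
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        if self.event_rate_hz < 0 or self.noise_sd < 0:
            raise ValueError("event rate and noise SD must be >= 0")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if self.stimulus_time_s is not None and not (
            0.0 <= self.stimulus_time_s < self.duration_s
        ):
            raise ValueError("stimulus_time_s outside the recording")


def _kernel(t: np.ndarray, onset: float, amp: float, rise: float, decay: float
            ) -> np.ndarray:
    """Linear rise to ``amp`` over ``rise`` s, then exponential decay."""
    out = np.zeros_like(t)
    peak_t = onset + rise
    rising = (t >= onset) & (t < peak_t)
    if rise > 0:
        out[rising] = amp * (t[rising] - onset) / rise
    falling = t >= peak_t
    out[falling] = amp * np.exp(-(t[falling] - peak_t) / decay)
    return out


def gen_traces(cfg: TraceSimConfig):
    """Generate (TraceSet, truth event table).

    Event onsets per ROI follow a Poisson process with rate
    ``event_rate_hz``; truth rows carry onset/peak times and amplitude, with
    ``is_stimulus`` marking the planted depolarization response.
    """
    n_samples = int(round(cfg.duration_s * cfg.sampling_hz))
    t = np.arange(n_samples) / cfg.sampling_hz
    sel_rng = _rng(cfg.seed, 0)
    responders = (
        sel_rng.random(cfg.n_rois) < cfg.responder_fraction
        if cfg.stimulus_time_s is not None
        else np.zeros(cfg.n_rois, dtype=bool)
    )
    traces = {}
    truth_rows = []
    for r in range(cfg.n_rois):
        roi = f"ROI{r:04d}"
        rrng = _rng(cfg.seed, 1, r)
        n_events = rrng.poisson(cfg.event_rate_hz * cfg.duration_s)
        onsets = np.sort(rrng.uniform(0.0, cfg.duration_s, size=n_events))
        x = np.zeros(n_samples)
        for onset in onsets:
            x += _kernel(t, onset, cfg.amplitude_dff, cfg.rise_s, cfg.decay_s)
            truth_rows.append({
                "roi": roi, "onset_s": onset, "peak_s": onset + cfg.rise_s,
                "amplitude": cfg.amplitude_dff, "is_stimulus": False,
            })
        if cfg.stimulus_time_s is not None and responders[r]:
            x += _kernel(t, cfg.stimulus_time_s, cfg.stim_amplitude_dff,
                         cfg.rise_s, cfg.decay_s)
            truth_rows.append({
                "roi": roi, "onset_s": cfg.stimulus_time_s,
                "peak_s": cfg.stimulus_time_s + cfg.rise_s,
                "amplitude": cfg.stim_amplitude_dff, "is_stimulus": True,
            })
        if cfg.noise_sd > 0:
            x = x + rrng.normal(0.0, cfg.noise_sd, size=n_samples)
        traces[roi] = x
    ts = TraceSet(
        time=t,
        traces=pd.DataFrame(traces),
        sampling_hz=cfg.sampling_hz,
        stimulus_time_s=cfg.stimulus_time_s,
    )
    truth = pd.DataFrame(
        truth_rows, columns=["roi", "onset_s", "peak_s", "amplitude", "is_stimulus"]
    )
    return ts, truth


def gen_ct_table(
    genes: Sequence[str],
    conditions: Sequence[str],
    true_fold_changes: Mapping[str, Mapping[str, float]],
    ref_genes: Sequence[str] = ("GAPDH", "TBP"),
    ct_noise_sd: float = 0.0,
    n_bio_reps: int = 3,
    n_tech_reps: int = 2,
    control_condition: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table whose noiseless 2^-ΔΔCt analysis recovers the planted folds.

    ``true_fold_changes[gene][condition]`` is the planted fold relative to
    the control condition (default: the first condition, fold 1 implied).
    Reference genes get fixed Cts (so fold 1 holds for them by
    construction); target Cts are base − log2(fold), plus optional noise.
    """
    control = control_condition or conditions[0]
    if control not in conditions:
        raise ValueError("control condition must appear in conditions")
    ref_base = {g: 19.0 + 2.0 * i for i, g in enumerate(ref_genes)}
    rng = _rng(seed, 0)
    rows = []
    base_ct = {g: 24.0 + 0.5 * i for i, g in enumerate(genes)}
    for cond in conditions:
        for b in range(n_bio_reps):
            sample = f"{cond}_B{b}"
            for gene in list(ref_genes) + list(genes):
                if gene in ref_base:
                    true_ct = ref_base[gene]
                else:
                    fold = 1.0
                    if cond != control:
                        fold = float(true_fold_changes.get(gene, {}).get(cond, 1.0))
                        if fold <= 0:
                            raise ValueError(f"nonpositive fold change for {gene!r}")
                    true_ct = base_ct[gene] - np.log2(fold)
                for trep in range(n_tech_reps):
                    noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                    rows.append({
                        "gene": gene, "sample": sample, "condition": cond,
                        "replicate": f"t{trep}", "ct": true_ct + noise,
                    })
    return pd.DataFrame(rows)


def write_study(
    out_dir: str | Path,
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    truth: pd.DataFrame | None = None,
) -> None:
    """Write the standard expression pipeline inputs as TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(out / "expression.tsv", sep="\t", index_label="gene")
    samples.to_csv(out / "samples.tsv", sep="\t", index_label="sample")
    if truth is not None:
        truth.to_csv(out / "truth_de_genes.tsv", sep="\t", index=False)
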