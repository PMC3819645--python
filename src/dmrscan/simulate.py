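"""Synthetic bisulfite methylome, segmentation and expression generators.

The generator emulates the statistical structure of a pooled two-sample
whole-genome bisulfite experiment on a homogeneous tissue:

* CpG positions with geometric (memoryless) inter-site gaps, mean 100 bp;
* a bimodal per-CpG methylation landscape from a three-component beta
  mixture (defaults ~10% unmethylated, ~40% partial, ~50% fully methylated
  under the 0.05/0.95 cuts), shared between the two samples;
* localized differentially methylated regions (<150 bp) planted in
  island-like CpG-dense stretches, where the old sample's true ratio is
  shifted by +/-delta (clipped to [0, 1]);
* strand-specific binomial call counts at Poisson coverage per sample
  (defaults 11.3x young, 11.9x old);
* an unmethylated mitochondria-like control contig whose residual C calls
  reflect the configured bisulfite conversion error, for conversion-rate QC;
* optional non-CpG cytosine records (essentially unmethylated) for
  CpG-specificity QC.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import IntervalTrack, MethylomeTable

__all__ = [
    "DmrPlan",
    "SyntheticSpec",
    "SyntheticTruth",
    "simulate_methylomes",
    "simulate_segmentation",
    "simulate_expression",
    "evaluate_dmr_recovery",
    "RecoveryResult",
]


@dataclass
class DmrPlan:
    """Plan for planting true DMRs.

    DMRs are placed in locally CpG-dense (island-like) stretches: with the
    genome-wide mean spacing of 100 bp a 150-bp window would hold only ~1.5
    CpGs, whereas real regulatory DMRs sit in CpG-dense sequence.
    ``island_spacing`` is the mean CpG gap inside a planted DMR.
    """

    n_dmrs: int = 50
    width: int = 150
    delta: float = 0.4
    frac_hyper: float = 0.5
    min_cpgs: int = 10
    island_spacing: float = 10.0
    min_separation: int = 2000


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic two-sample methylome experiment."""

    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 20_000_000})
    mean_spacing: float = 100.0
    mixture_weights: tuple = (0.10, 0.40, 0.50)
    beta_params: tuple = ((1.0, 100.0), (5.0, 5.0), (100.0, 1.0))
    coverage_young: float = 11.3
    coverage_old: float = 11.9
    dmr_plan: DmrPlan = field(default_factory=DmrPlan)
    control_contig: str = "chrM"
    control_length: int = 16_571
    control_sites: int = 500
    conversion_error_young: float = 0.0016
    conversion_error_old: float = 0.0012
    noncpg_sites: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not 0 < self.dmr_plan.delta <= 1:
            raise ValueError("DMR delta must be in (0, 1]")

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated experiment: planted DMRs and true ratios."""

    dmrs: pd.DataFrame  # chrom, start, end, direction, delta, n_cpgs
    true_ratios: pd.DataFrame  # chrom, pos, ratio_young, ratio_old
    spec: SyntheticSpec


class DmrPlacementError(RuntimeError):
    """Raised when the DMR plan cannot be satisfied."""


def _geometric_positions(rng: np.random.Generator, length: int, mean_gap: float) -> np.ndarray:
    """1-based cytosine positions with geometric gaps, keeping pos+1 on-contig."""
    positions = []
    cur = 0
    block = max(16, int(length / mean_gap * 1.2) + 16)
    while cur < length - 1:
        gaps = rng.geometric(1.0 / mean_gap, size=block)
        cum = cur + np.cumsum(gaps)
        positions.append(cum[cum <= length - 1])
        cur = int(cum[-1])
    return np.concatenate(positions) if positions else np.array([], dtype=np.int64)


def _place_dmrs(rng: np.random.Generator, spec: SyntheticSpec) -> pd.DataFrame:
    plan = spec.dmr_plan
    chroms = list(spec.chrom_sizes)
    sizes = np.array([spec.chrom_sizes[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    unplaced = []
    for i in range(plan.n_dmrs):
        ok = False
        for _ in range(1000):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            length = spec.chrom_sizes[chrom]
            if length < plan.width + 2 * plan.min_separation:
                continue
            start = int(
                rng.integers(plan.min_separation, length - plan.width - plan.min_separation)
            )
            end = start + plan.width
            if all(
                end + plan.min_separation <= s or start >= e + plan.min_separation
                for s, e in placed[chrom]
            ):
                placed[chrom].append((start, end))
                hyper = rng.random() < plan.frac_hyper
                rows.append(
                    (chrom, start, end, "hyper_old" if hyper else "hypo_old", plan.delta)
                )
                ok = True
                break
        if not ok:
            unplaced.append(i)
    if unplaced:
        raise DmrPlacementError(f"could not place DMRs: indices {unplaced}")
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "delta"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def _sample_mixture(rng: np.random.Generator, spec: SyntheticSpec, n: int) -> np.ndarray:
    comp = rng.choice(len(spec.mixture_weights), size=n, p=list(spec.mixture_weights))
    out = np.empty(n)
    for ci, (a, b) in enumerate(spec.beta_params):
        sel = comp == ci
        out[sel] = rng.beta(a, b, size=int(sel.sum()))
    return out


def _strand_records(
    rng: np.random.Generator,
    chrom: str,
    pos: np.ndarray,
    true_young: np.ndarray,
    true_old: np.ndarray,
    spec: SyntheticSpec,
    context: str = "CG",
) -> tuple[list[pd.DataFrame], list[pd.DataFrame]]:
    """Emit independent +/- strand count records for both samples."""
    young_frames, old_frames = [], []
    for strand, strand_pos in (("+", pos), ("-", pos + 1)):
        for frames, mean_cov, true in (
            (young_frames, spec.coverage_young, true_young),
            (old_frames, spec.coverage_old, true_old),
        ):
            cov = rng.poisson(mean_cov, size=len(pos))
            meth = rng.binomial(cov, true)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": strand_pos,
                        "strand": strand,
                        "context": context,
                        "n_meth": meth,
                        "n_total": cov,
                    }
                )
            )
    return young_frames, old_frames


def simulate_methylomes(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[MethylomeTable, MethylomeTable, SyntheticTruth]:
    """Generate a (young, old) methylome pair plus its ground truth.

    Both strands of every CpG are emitted with independent Poisson coverage
    and binomial methylated-call counts around a shared true ratio; inside
    planted DMRs the old sample's true ratio is shifted by the plan's
    +/-delta (clipped to [0, 1]) and the baseline is drawn from the partial
    (mid) mixture component, where age-related variation plausibly lives and
    where a shift survives clipping.
    """
    if seed is not None:
        spec = spec.with_seed(seed)
    rng = np.random.default_rng(spec.seed)
    truth_dmrs = (
        _place_dmrs(rng, spec)
        if spec.dmr_plan.n_dmrs > 0
        else pd.DataFrame(columns=["chrom", "start", "end", "direction", "delta"])
    )

    young_frames: list[pd.DataFrame] = []
    old_frames: list[pd.DataFrame] = []
    truth_rows = []
    n_cpgs_per_dmr = {}
    mid_a, mid_b = spec.beta_params[1]

    for chrom in sorted(spec.chrom_sizes):
        length = spec.chrom_sizes[chrom]
        pos = _geometric_positions(rng, length, spec.mean_spacing)
        dmrs_here = truth_dmrs[truth_dmrs["chrom"] == chrom]
        island_pos = []
        for di, d in dmrs_here.iterrows():
            plan = spec.dmr_plan
            n_island = max(plan.min_cpgs, int(rng.poisson(plan.width / plan.island_spacing)))
            n_island = min(n_island, plan.width - 1)
            offsets = np.sort(rng.choice(plan.width - 1, size=n_island, replace=False))
            island_pos.append(int(d["start"]) + 1 + offsets)  # 1-based positions in span
        if island_pos:
            pos = np.concatenate([pos] + island_pos)
        pos = np.unique(pos).astype(np.int64)

        base = _sample_mixture(rng, spec, len(pos))
        old_true = base.copy()
        in_any = np.zeros(len(pos), dtype=bool)
        for di, d in dmrs_here.iterrows():
            inside = (pos - 1 >= d["start"]) & (pos - 1 < d["end"])
            # partial-methylation baseline inside DMRs: a +/-delta shift on a
            # near-0/near-1 baseline would be erased by clipping
            base[inside] = rng.beta(mid_a, mid_b, size=int(inside.sum()))
            sign = 1.0 if d["direction"] == "hyper_old" else -1.0
            old_true[inside] = np.clip(base[inside] + sign * d["delta"], 0.0, 1.0)
            n_cpgs_per_dmr[di] = int(inside.sum())
            in_any |= inside
        old_true[~in_any] = base[~in_any]

        yf, of = _strand_records(rng, chrom, pos, base, old_true, spec)
        young_frames += yf
        old_frames += of
        truth_rows.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "ratio_young": base, "ratio_old": old_true}
            )
        )

        if spec.noncpg_sites > 0:
            n_nc = spec.noncpg_sites
            nc_pos = rng.choice(length - 1, size=min(n_nc, length // 4), replace=False) + 1
            nc_pos = np.setdiff1d(nc_pos, np.concatenate([pos, pos + 1]))
            ctx = np.where(rng.random(len(nc_pos)) < 0.5, "CHG", "CHH")
            for frames, mean_cov, err in (
                (young_frames, spec.coverage_young, spec.conversion_error_young),
                (old_frames, spec.coverage_old, spec.conversion_error_old),
            ):
                cov = rng.poisson(mean_cov, size=len(nc_pos))
                meth = rng.binomial(cov, err)
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": nc_pos,
                            "strand": "+",
                            "context": ctx,
                            "n_meth": meth,
                            "n_total": cov,
                        }
                    )
                )

    if spec.control_sites > 0:
        step = max(1, spec.control_length // (spec.control_sites + 1))
        cpos = (np.arange(1, spec.control_sites + 1) * step).astype(np.int64)
        cpos = cpos[cpos < spec.control_length]
        for frames, mean_cov, err in (
            (young_frames, spec.coverage_young, spec.conversion_error_young),
            (old_frames, spec.coverage_old, spec.conversion_error_old),
        ):
            cov = rng.poisson(mean_cov, size=len(cpos))
            meth = rng.binomial(cov, err)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": spec.control_contig,
                        "pos": cpos,
                        "strand": "+",
                        "context": "CG",
                        "n_meth": meth,
                        "n_total": cov,
                    }
                )
            )

    young = MethylomeTable(
        pd.concat(young_frames, ignore_index=True), sample="young", build="synthetic"
    )
    old = MethylomeTable(
        pd.concat(old_frames, ignore_index=True), sample="old", build="synthetic"
    )
    truth_dmrs = truth_dmrs.assign(
        n_cpgs=[n_cpgs_per_dmr.get(i, 0) for i in truth_dmrs.index]
    )
    truth = SyntheticTruth(
        dmrs=truth_dmrs.reset_index(drop=True),
        true_ratios=pd.concat(truth_rows, ignore_index=True)
        if truth_rows
        else pd.DataFrame(columns=["chrom", "pos", "ratio_young", "ratio_old"]),
        spec=spec,
    )
    return young, old, truth


def simulate_segmentation(
    chrom_sizes: dict,
    states: tuple = ("Promoter", "Enhancer", "Transcribed", "Heterochrom", "Quiescent"),
    mean_segment: int = 20_000,
    seed: int = 0,
) -> IntervalTrack:
    """A toy chromatin-state segmentation: exponential segment lengths, iid labels."""
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in sorted(chrom_sizes):
        length = chrom_sizes[chrom]
        cur = 0
        while cur < length:
            seg = int(rng.exponential(mean_segment)) + 200
            end = min(cur + seg, length)
            rows.append((chrom, cur, end, states[int(rng.integers(len(states)))]))
            cur = end
    return IntervalTrack(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]),
        name="synthetic_segmentation",
    )


def simulate_expression(
    n_genes: int = 15,
    n_per_group: int = 9,
    effects: float | np.ndarray = 1.0,
    noise_sd: float = 0.5,
    n_replicates: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format synthetic delta-Ct table for two age groups.

    delta-Ct = per-gene baseline + group effect (added to the old group;
    positive effect = lower expression in old) + Gaussian noise per replicate.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    effects = np.broadcast_to(np.asarray(effects, dtype=float), (n_genes,))
    baselines = rng.uniform(2.0, 10.0, size=n_genes)
    rows = []
    subjects = [(f"young_{i+1:02d}", "young") for i in range(n_per_group)] + [
        (f"old_{i+1:02d}", "old") for i in range(n_per_group)
    ]
    for g in range(n_genes):
        gene = f"G{g+1:03d}"
        for subject, group in subjects:
            shift = effects[g] if group == "old" else 0.0
            for rep in range(1, n_replicates + 1):
                val = baselines[g] + shift + rng.normal(0.0, noise_sd)
                rows.append((gene, subject, group, rep, val))
    return pd.DataFrame(
        rows, columns=["gene", "subject", "group", "replicate", "delta_ct"]
    )


@dataclass
class RecoveryResult:
    """Precision/recall of called DMRs against planted truth."""

    precision: float | None
    recall: float | None
    n_called: int
    n_truth: int
    called: pd.DataFrame  # with 'matched' flag
    truth: pd.DataFrame  # with 'recovered' flag


def _overlap_flags(
    query: pd.DataFrame, target: pd.DataFrame
) -> np.ndarray:
    """Per query row: overlaps (>=1 bp) any target row of the same direction."""
    flags = np.zeros(len(query), dtype=bool)
    for direction in ("hyper_old", "hypo_old"):
        tgt = target[target["direction"] == direction]
        q = query["direction"].to_numpy() == direction
        if tgt.empty or not q.any():
            continue
        track = IntervalTrack(
            tgt.assign(label=direction)[["chrom", "start", "end", "label"]]
        )
        flags[q] = track.overlaps_intervals(
            query.loc[q, "chrom"].to_numpy(),
            query.loc[q, "start"].to_numpy(),
            query.loc[q, "end"].to_numpy(),
        )
    return flags


def evaluate_dmr_recovery(called: pd.DataFrame, truth: SyntheticTruth) -> RecoveryResult:
    """Match called DMRs to planted truth (>=1 bp overlap, direction agreement).

    One-to-many matches count once per side: a called DMR is a true positive
    when it touches any same-direction truth DMR, and a truth DMR counts as
    recovered when any same-direction call touches it.
    """
    truth_dmrs = truth.dmrs
    called = called.reset_index(drop=True)
    matched = (
        _overlap_flags(called, truth_dmrs) if len(called) and len(truth_dmrs)
        else np.zeros(len(called), dtype=bool)
    )
    recovered = (
        _overlap_flags(truth_dmrs, called) if len(called) and len(truth_dmrs)
        else np.zeros(len(truth_dmrs), dtype=bool)
    )
    precision = float(matched.mean()) if len(called) else None
    recall = float(recovered.mean()) if len(truth_dmrs) else None
    return RecoveryResult(
        precision=precision,
        recall=recall,
        n_called=len(called),
        n_truth=len(truth_dmrs),
        called=called.assign(matched=matched),
        truth=truth_dmrs.assign(recovered=recovered),
    )
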