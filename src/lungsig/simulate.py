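"""Synthetic two-study expression cohorts with planted, recoverable signal.

The generator emulates the structure of the study's training cohorts: one
study contributing IPF patients and a few healthy controls, a second study
contributing NSCLC patients and many healthy controls, both on a shared
gene universe. Ground truth records which genes carry disease effects,
which are shared between the diseases, and which sample subsets realize
the planted mutually exclusive alteration pairs, so every downstream stage
(merging, DEG screening, SVM weighting, signature selection, exclusivity
testing) has a known answer.

Model, on the log2 scale:

* per-gene baseline means shared across studies (drawn once);
* additive Gaussian noise with SD ``noise_sd``;
* per-study, per-gene affine batch distortion
  ``x -> scale_g * x + shift_g`` with shift SD ``batch_shift_sd`` and scale
  drawn uniformly from ``batch_scale_range``;
* differential genes shifted by ``±de_effect`` in their disease group only,
  a configurable subset of them shared (same sign) between the diseases;
* mutually exclusive pairs realized as direction-consistent expression
  excursions on disjoint disease-sample subsets.

Each study consumes an independent RNG stream spawned from the master seed,
so adding a study never perturbs earlier studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = ["StudyDesign", "SimulationConfig", "GroundTruth", "simulate_cohorts"]


@dataclass
class StudyDesign:
    """Sample counts per phenotype for one simulated study."""

    study_id: str
    groups: dict[str, int]  # phenotype -> sample count


def default_studies() -> list[StudyDesign]:
    # Cohort shapes of the two training studies: 17 IPF / 6 healthy and
    # 46 NSCLC / 45 healthy.
    return [
        StudyDesign("studyA", {"IPF": 17, "healthy": 6}),
        StudyDesign("studyB", {"NSCLC": 46, "healthy": 45}),
    ]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the planted-signal regime the pipeline is tested
    against: strong differential genes (log2 effect 2.0 against noise SD
    0.5), per-gene batch shifts comparable to the biological effect, and
    mutually exclusive pairs covering the disease cohorts.
    """

    n_genes: int = 1000
    studies: list[StudyDesign] = field(default_factory=default_studies)
    n_de_genes: dict[str, int] = field(default_factory=lambda: {"IPF": 100, "NSCLC": 100})
    n_common_de: int = 40
    de_effect: float = 2.0
    noise_sd: float = 0.5
    batch_shift_sd: float = 0.8
    batch_scale_range: tuple[float, float] = (0.8, 1.25)
    n_mutex_pairs: int = 2
    mutex_coverage: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 < self.mutex_coverage <= 0.5:
            raise ValueError("mutex_coverage must lie in (0, 0.5] so a pair's two "
                             "disjoint altered sets fit in the cohort")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        diseases = self.diseases()
        if self.n_common_de > min((self.n_de_genes.get(d, 0) for d in diseases), default=0) \
                and diseases:
            raise ValueError("n_common_de exceeds a disease's n_de_genes")
        needed = self.n_common_de + 2 * self.n_mutex_pairs + sum(
            self.n_de_genes.get(d, 0) - self.n_common_de for d in diseases
        )
        if needed > self.n_genes:
            raise ValueError(
                f"planted genes ({needed}) exceed n_genes ({self.n_genes})")
        for s in self.studies:
            for pheno, n in s.groups.items():
                if n < 1:
                    raise ValueError(f"{s.study_id}:{pheno} sample count must be >= 1")

    def diseases(self) -> list[str]:
        seen: list[str] = []
        for s in self.studies:
            for pheno in s.groups:
                if pheno != "healthy" and pheno not in seen:
                    seen.append(pheno)
        return seen


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort set.

    ``de_genes`` maps disease -> {gene: +1/-1} (sign of the disease shift);
    ``common_de_genes`` is the subset planted with identical sign in every
    disease; ``mutex_pairs`` maps disease -> list of
    ``(gene_a, gene_b, samples_a, samples_b, direction)`` with disjoint
    sample ID lists; ``batch`` maps study -> per-gene shift/scale arrays.
    """

    de_genes: dict[str, dict[str, int]]
    common_de_genes: dict[str, int]
    mutex_pairs: dict[str, list[tuple]]
    batch: dict[str, dict[str, list[float]]]

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1))


# Disease-wide baseline shift (in noise-SD units) carried by mutex-pair
# genes, and the extra excursion applied to their altered samples. The
# combination places altered samples ~4.25 SD and non-altered samples
# < 1.9 SD from the control mean, so a 2-SD binarization rule recovers the
# planted pattern exactly; the baseline also gives the gene enough
# disease-axis correlation to survive the loading-threshold filter.
_MUTEX_BASE_SD = 1.25
_MUTEX_EXTRA_SD = 3.0
_MUTEX_NOISE_CLIP_SD = 0.6


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[dict[str, ExpressionMatrix], pd.DataFrame, GroundTruth]:
    """Simulate per-study expression matrices with known ground truth.

    Returns
    -------
    studies
        Mapping study_id -> :class:`ExpressionMatrix` (log2 scale, batch
        distortion applied).
    sample_sheet
        Concatenated sheet over all studies (sample_id index; study_id,
        phenotype columns).
    truth
        :class:`GroundTruth` describing every planted effect.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    # one stream for the shared gene-level draws, one per study
    gene_ss, *study_ss = master.spawn(1 + len(config.studies))
    gene_rng = np.random.default_rng(gene_ss)

    genes = pd.Index([f"G{i:05d}" for i in range(config.n_genes)], name="gene")
    baseline = gene_rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)

    diseases = config.diseases()
    truth = _plant_gene_effects(config, diseases, genes, gene_rng)

    # per-disease additive effect vectors (log2 shift applied to disease samples)
    effect = {d: np.zeros(config.n_genes) for d in diseases}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for d in diseases:
        for g, sign in truth.de_genes[d].items():
            effect[d][gene_pos[g]] = sign * config.de_effect
        for ga, gb, _, _, sign in truth.mutex_pairs.get(d, []):
            for g in (ga, gb):
                effect[d][gene_pos[g]] = sign * _MUTEX_BASE_SD * config.noise_sd

    studies: dict[str, ExpressionMatrix] = {}
    sheets = []
    batch: dict[str, dict[str, list[float]]] = {}
    mutex_sample_sets = _assign_mutex_samples(config, diseases, truth, study_ss)

    for design, ss in zip(config.studies, study_ss):
        rng = np.random.default_rng(ss)
        shift = rng.normal(0.0, config.batch_shift_sd, config.n_genes)
        scale = rng.uniform(*config.batch_scale_range, config.n_genes)
        batch[design.study_id] = {"shift": shift.tolist(), "scale": scale.tolist()}

        cols, phenos = [], []
        blocks = []
        for pheno, n in design.groups.items():
            ids = [f"{design.study_id}_{pheno}_{i:03d}" for i in range(n)]
            cols += ids
            phenos += [pheno] * n
            mean = np.broadcast_to(
                baseline[:, None]
                + (effect[pheno][:, None] if pheno in effect else 0.0),
                (config.n_genes, n),
            )
            noise = rng.normal(0.0, config.noise_sd, (config.n_genes, n))
            block = mean + noise
            if pheno in diseases:
                block = _apply_mutex(
                    block, ids, truth.mutex_pairs.get(pheno, []), gene_pos,
                    config.noise_sd, mean, noise,
                )
            blocks.append(block)
        clean = np.hstack(blocks)
        distorted = scale[:, None] * clean + shift[:, None]
        values = pd.DataFrame(distorted, index=genes, columns=cols)
        sheet = pd.DataFrame(
            {"study_id": design.study_id, "phenotype": phenos},
            index=pd.Index(cols, name="sample_id"),
        )
        studies[design.study_id] = ExpressionMatrix(values, sheet)
        sheets.append(sheet)

    truth.batch = batch
    # record realized mutex sample IDs
    for d in diseases:
        truth.mutex_pairs[d] = mutex_sample_sets[d]
    sample_sheet = pd.concat(sheets)
    return studies, sample_sheet, truth


def _plant_gene_effects(config, diseases, genes, rng) -> GroundTruth:
    """Choose DE genes, shared genes and mutex-pair genes (disjoint sets)."""
    n_common = config.n_common_de if diseases else 0
    cursor = 0
    common = list(genes[cursor:cursor + n_common]); cursor += n_common
    common_sign = {g: int(s) for g, s in zip(common, rng.choice([-1, 1], n_common))}

    mutex_genes = list(genes[cursor:cursor + 2 * config.n_mutex_pairs])
    cursor += 2 * config.n_mutex_pairs
    pair_sign = rng.choice([-1, 1], config.n_mutex_pairs)

    de: dict[str, dict[str, int]] = {}
    for d in diseases:
        n_specific = config.n_de_genes.get(d, 0) - n_common
        specific = list(genes[cursor:cursor + n_specific]); cursor += n_specific
        signs = rng.choice([-1, 1], n_specific)
        de[d] = dict(common_sign)
        de[d].update({g: int(s) for g, s in zip(specific, signs)})

    pairs: dict[str, list[tuple]] = {
        d: [
            (mutex_genes[2 * i], mutex_genes[2 * i + 1], None, None, int(pair_sign[i]))
            for i in range(config.n_mutex_pairs)
        ]
        for d in diseases
    }
    return GroundTruth(de_genes=de, common_de_genes=common_sign,
                       mutex_pairs=pairs, batch={})


def _assign_mutex_samples(config, diseases, truth, study_ss):
    """Assign disjoint altered-sample ID sets for each pair, per disease."""
    assignments: dict[str, list[tuple]] = {d: [] for d in diseases}
    for design, ss in zip(config.studies, study_ss):
        rng = np.random.default_rng(ss.spawn(1)[0])
        for pheno, n in design.groups.items():
            if pheno not in diseases:
                continue
            ids = np.array([f"{design.study_id}_{pheno}_{i:03d}" for i in range(n)])
            k = max(1, int(round(config.mutex_coverage * n)))
            k = min(k, n // 2)  # two disjoint sets must fit
            for ga, gb, _, _, sign in truth.mutex_pairs[pheno]:
                perm = rng.permutation(n)
                sa = sorted(ids[perm[:k]].tolist())
                sb = sorted(ids[perm[k:2 * k]].tolist())
                assignments[pheno].append((ga, gb, sa, sb, sign))
    # stash on truth so _apply_mutex can see sample IDs
    for d in diseases:
        truth.mutex_pairs[d] = assignments[d]
    return assignments


def _apply_mutex(block, ids, pairs, gene_pos, noise_sd, mean, noise):
    """Realize planted alterations: excursions on altered samples, clipped
    noise on the rest so the pair binarizes with zero co-altered samples."""
    id_pos = {s: j for j, s in enumerate(ids)}
    for ga, gb, sa, sb, sign in pairs:
        for g, altered in ((ga, sa), (gb, sb)):
            gi = gene_pos[g]
            alt_cols = [id_pos[s] for s in altered if s in id_pos]
            if not alt_cols:
                continue  # this pair realization belongs to another study
            other = [j for j in range(len(ids)) if j not in set(alt_cols)]
            # non-altered disease samples: truncate noise so they stay
            # inside the binarization band
            clipped = np.clip(noise[gi, other], -_MUTEX_NOISE_CLIP_SD * noise_sd,
                              _MUTEX_NOISE_CLIP_SD * noise_sd)
            block[gi, other] = mean[gi, other] + clipped
            block[gi, alt_cols] += sign * _MUTEX_EXTRA_SD * noise_sd
    return block


def write_cohorts(
    studies: dict[str, ExpressionMatrix],
    sample_sheet: pd.DataFrame,
    truth: GroundTruth,
    outdir: str | Path,
) -> None:
    """Write expression TSVs, the sample sheet and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, em in studies.items():
        em.to_tsv(outdir / f"expression_{sid}.tsv")
    sheet = sample_sheet.reset_index()
    sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    truth.to_json(outdir / "ground_truth.json")
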