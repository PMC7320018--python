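"""Synthetic labeled multi-omics cohorts with planted discriminative genes.

The generator emulates the statistical structure of a breast-cancer cohort
profiled on three omics layers: RNA isoform expression, miRNA expression and
array methylation from two platforms. Each patient carries ER/PR/HER2
receptor calls; triple-negative (TNBC) patients — all three receptors
negative — form the positive class, about 16% of the cohort, with the
remainder split across Luminal A, Luminal B and HER2-enriched subtypes.

Background attributes are class-independent Gaussian draws on a log-like
continuous scale. A configurable number of *planted* attributes receive a
standardized class-mean shift of ``±effect_size * noise_sd`` in the TNBC
class (up- or down-regulated), one isoform per planted gene; their
identities and directions are returned as ground truth so that recovery of
the discriminative genes can be scored. Missing values are confined to the
methylation views. One master seed spawns an independent substream per
view (keyed by view name), so adding or removing a view never perturbs the
values generated for the others.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .views import OmicsView

__all__ = [
    "ReceptorStatus",
    "CohortConfig",
    "ClinicalRecord",
    "PlantedSignal",
    "LabeledCohort",
    "derive_subtype",
    "generate_cohort",
    "allocate_counts",
    "write_cohort",
    "FULL_SCALE_VIEW_WIDTHS",
]

Subtype = Literal["TNBC", "LuminalA", "LuminalB", "HER2"]
Direction = Literal["up_in_tnbc", "down_in_tnbc"]

#: View widths matching the published cohort: 73,599 RNA isoforms, 1,046
#: miRNAs, and two methylation platforms whose probe union is 23,381.
FULL_SCALE_VIEW_WIDTHS: dict[str, int] = {
    "isoform": 73_599,
    "mirna": 1_046,
    "methyl_450": 21_000,
    "methyl_27": 4_000,
}
FULL_SCALE_SHARED_PROBES = 1_619  # 21,000 + 4,000 - 1,619 = 23,381


@dataclass(frozen=True)
class ReceptorStatus:
    """Immunohistochemistry-style receptor calls; True = positive."""

    er: bool
    pr: bool
    her2: bool


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    receptors: ReceptorStatus
    subtype: Subtype
    label: int  # 1 = TNBC


@dataclass(frozen=True)
class PlantedSignal:
    """Ground truth for one planted discriminative attribute."""

    attribute_id: str
    view: str
    gene_symbol: str
    direction: Direction
    effect_size: float


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters; defaults encode the published cohort's shape.

    ``subtype_fractions`` default to 16% TNBC / 63% Luminal A / 16% Luminal B /
    5% HER2; at ``n_samples=877`` largest-remainder rounding yields 140 TNBC
    and 737 non-TNBC patients. ``n_planted_down``/``n_planted_up`` plant one
    shifted isoform in each of that many distinct genes (defaults 15 and 5,
    the split reported for the discriminative gene list). ``effect_size`` is
    the standardized class-mean shift delta (unitless, in units of
    ``noise_sd``).
    """

    n_samples: int = 877
    subtype_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "TNBC": 0.16,
            "LuminalA": 0.63,
            "LuminalB": 0.16,
            "HER2": 0.05,
        }
    )
    view_widths: Mapping[str, int] = field(
        default_factory=lambda: dict(FULL_SCALE_VIEW_WIDTHS)
    )
    shared_methyl_probes: int = FULL_SCALE_SHARED_PROBES
    isoforms_per_gene: int = 4
    n_planted_down: int = 15
    n_planted_up: int = 5
    effect_size: float = 2.0
    noise_sd: float = 1.0
    missing_rate: float = 0.1
    planted_view: str = "isoform"
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.subtype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.subtype_fractions.values()):
            raise ValueError("subtype fractions must be non-negative")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.isoforms_per_gene < 1:
            raise ValueError("isoforms_per_gene must be >= 1")
        n_planted = self.n_planted_down + self.n_planted_up
        if self.planted_view not in self.view_widths and n_planted > 0:
            raise ValueError(f"planted view {self.planted_view!r} not among views")
        if n_planted > 0:
            width = self.view_widths[self.planted_view]
            n_genes = -(-width // self.isoforms_per_gene)
            if n_planted > n_genes:
                raise ValueError(
                    f"{n_planted} planted genes requested but the "
                    f"{self.planted_view!r} view only holds {n_genes} genes"
                )
        if n_planted * 2 > sum(self.view_widths.values()):
            raise ValueError("more planted attributes requested than attributes exist")
        for name in ("methyl_450", "methyl_27"):
            if name in self.view_widths and self.shared_methyl_probes > self.view_widths[name]:
                raise ValueError("shared_methyl_probes exceeds a platform's width")


@dataclass
class LabeledCohort:
    records: list[ClinicalRecord]
    views: dict[str, OmicsView]

    @property
    def sample_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)


def derive_subtype(receptors: ReceptorStatus) -> tuple[Subtype, int]:
    """Clinical subtype and binary TNBC label from the three receptor calls.

    Triple-negative (ER-, PR-, HER2-) -> TNBC, label 1. Otherwise label 0
    with subtype Luminal A (ER+ and/or PR+, HER2-), Luminal B (ER+ and/or
    PR+, HER2+) or HER2-enriched (ER-, PR-, HER2+). Total over all eight
    receptor combinations.
    """
    hormone_positive = receptors.er or receptors.pr
    if hormone_positive:
        return ("LuminalB" if receptors.her2 else "LuminalA"), 0
    if receptors.her2:
        return "HER2", 0
    return "TNBC", 1


def allocate_counts(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` samples across subtypes.

    Each subtype gets floor(n * fraction); the leftover slots go to the
    subtypes with the largest fractional remainders (ties broken by larger
    fraction, then name), so counts always sum to ``n`` and never deviate
    from ``n * fraction`` by more than 1.
    """
    exact = {k: n * f for k, f in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in exact.items()}
    leftover = n - sum(counts.values())
    by_remainder = sorted(
        fractions, key=lambda k: (-(exact[k] - counts[k]), -fractions[k], k)
    )
    for k in by_remainder[:leftover]:
        counts[k] += 1
    return counts


_RECEPTOR_CHOICES: dict[str, list[ReceptorStatus]] = {
    "TNBC": [ReceptorStatus(False, False, False)],
    "LuminalA": [
        ReceptorStatus(True, True, False),
        ReceptorStatus(True, False, False),
        ReceptorStatus(False, True, False),
    ],
    "LuminalB": [
        ReceptorStatus(True, True, True),
        ReceptorStatus(True, False, True),
        ReceptorStatus(False, True, True),
    ],
    "HER2": [ReceptorStatus(False, False, True)],
}


def _substream(seed: int, stream: str) -> np.random.Generator:
    # keyed by a stable CRC of the stream name so streams are independent of
    # the set of other streams drawn from the same master seed
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])


def _make_clinical(config: CohortConfig) -> list[ClinicalRecord]:
    rng = _substream(config.seed, "clinical")
    counts = allocate_counts(config.n_samples, config.subtype_fractions)
    subtypes: list[str] = []
    for k in config.subtype_fractions:  # stable order
        subtypes.extend([k] * counts[k])
    order = rng.permutation(config.n_samples)
    records = []
    width = len(str(config.n_samples))
    for i, pos in enumerate(order):
        subtype = subtypes[pos]
        choices = _RECEPTOR_CHOICES[subtype]
        receptors = choices[rng.integers(len(choices))]
        derived, label = derive_subtype(receptors)
        assert derived == subtype
        records.append(
            ClinicalRecord(
                patient_id=f"SYN-{i:0{width}d}",
                receptors=receptors,
                subtype=subtype,  # type: ignore[arg-type]
                label=label,
            )
        )
    return records


def _attribute_names(view: str, width: int, shared_offset: int | None = None) -> list[str]:
    if view.startswith("methyl"):
        start = shared_offset or 0
        return [f"cg{start + j:08d}" for j in range(width)]
    prefix = {"isoform": "iso", "mirna": "mir"}.get(view, view)
    return [f"{prefix}_{j:06d}" for j in range(width)]


def generate_cohort(config: CohortConfig) -> tuple[LabeledCohort, list[PlantedSignal]]:
    """Draw a labeled cohort and the manifest of its planted signals.

    Background values are N(0, noise_sd^2) per attribute, independent of
    class. Planted attributes get ``+effect_size * noise_sd`` (up_in_tnbc) or
    ``-effect_size * noise_sd`` (down_in_tnbc) added for TNBC samples.
    Methylation entries are masked missing independently at ``missing_rate``.
    The same config (including seed) reproduces the cohort bit for bit.
    """
    config.validate()
    records = _make_clinical(config)
    y = np.array([r.label for r in records], dtype=bool)
    sample_ids = [r.patient_id for r in records]

    # methylation platforms share a block of probe ids so they can be fused;
    # the 27K-style platform reuses the tail of the 450K-style probe range
    shared_offsets: dict[str, int] = {}
    if "methyl_450" in config.view_widths and "methyl_27" in config.view_widths:
        shared_offsets["methyl_450"] = 0
        shared_offsets["methyl_27"] = (
            config.view_widths["methyl_450"] - config.shared_methyl_probes
        )

    planted: list[PlantedSignal] = []
    views: dict[str, OmicsView] = {}
    for name, width in config.view_widths.items():
        rng = _substream(config.seed, f"view:{name}")
        attrs = _attribute_names(name, width, shared_offsets.get(name))
        values = rng.normal(0.0, config.noise_sd, size=(len(records), width))

        gene_map: dict[str, str | None] = {}
        if name == "isoform":
            for j, a in enumerate(attrs):
                gene_map[a] = f"GENE{j // config.isoforms_per_gene + 1:05d}"

        if name == config.planted_view:
            planted = _plant_signals(config, attrs, gene_map, values, y)

        missing = np.zeros_like(values, dtype=bool)
        if name.startswith("methyl") and config.missing_rate > 0:
            mrng = _substream(config.seed, f"missing:{name}")
            missing = mrng.random(values.shape) < config.missing_rate
        views[name] = OmicsView(
            name=name,
            sample_ids=sample_ids,
            attribute_ids=attrs,
            values=values,
            missing_mask=missing,
            gene_map=gene_map,
        )
    return LabeledCohort(records=records, views=views), planted


def _plant_signals(
    config: CohortConfig,
    attrs: list[str],
    gene_map: dict[str, str | None],
    values: np.ndarray,
    y: np.ndarray,
) -> list[PlantedSignal]:
    n_planted = config.n_planted_down + config.n_planted_up
    if n_planted == 0:
        return []
    rng = _substream(config.seed, "planted")
    n_genes = -(-len(attrs) // config.isoforms_per_gene)
    genes = rng.choice(n_genes, size=n_planted, replace=False)
    directions: list[Direction] = ["down_in_tnbc"] * config.n_planted_down + [
        "up_in_tnbc"
    ] * config.n_planted_up
    shift = config.effect_size * config.noise_sd
    planted = []
    for g, direction in zip(genes, directions):
        block = np.arange(
            g * config.isoforms_per_gene,
            min((g + 1) * config.isoforms_per_gene, len(attrs)),
        )
        j = int(rng.choice(block))
        sign = 1.0 if direction == "up_in_tnbc" else -1.0
        values[y, j] += sign * shift
        planted.append(
            PlantedSignal(
                attribute_id=attrs[j],
                view=config.planted_view,
                gene_symbol=gene_map.get(attrs[j]) or attrs[j],
                direction=direction,
                effect_size=config.effect_size,
            )
        )
    return planted


def write_cohort(cohort: LabeledCohort, planted: Sequence[PlantedSignal], outdir) -> None:
    """Write per-view matrices, the clinical table and the planted manifest."""
    from pathlib import Path

    from .views import write_view_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, view in cohort.views.items():
        write_view_tsv(view, out / f"{name}.tsv")
    with open(out / "clinical.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["patient_id", "er", "pr", "her2", "subtype", "label"])
        for r in cohort.records:
            w.writerow(
                [
                    r.patient_id,
                    "positive" if r.receptors.er else "negative",
                    "positive" if r.receptors.pr else "negative",
                    "positive" if r.receptors.her2 else "negative",
                    r.subtype,
                    r.label,
                ]
            )
    with open(out / "planted_signals.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["attribute_id", "view", "gene_symbol", "direction", "effect_size"])
        for p in planted:
            w.writerow([p.attribute_id, p.view, p.gene_symbol, p.direction, p.effect_size])
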