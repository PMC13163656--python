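"""Ensembles of five networks and thresholded recognition of genetic images.

A query image is evaluated once by each independently initialized member and
the per-organism activations are averaged. Organisms whose average meets the
recognition threshold (0.01 by default) are *recognized*; the best of them is
the *foreground* genetic image and the rest are *background* images. When
nothing reaches the threshold the best sub-threshold organism is still
reported, since very distant references can legitimately sit below 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import GeneticImage, OrganismRecord, ReferenceLengths, build_genetic_image
from .mlp import MLPConfig, MLPModel, forward, init_mlp, train_online

__all__ = [
    "Ensemble",
    "RecognitionReport",
    "teach_ensemble",
    "recognize",
    "default_hyper",
]

DEFAULT_MEMBERS = 5
RECOGNITION_THRESHOLD = 0.01

# teaching hyper-parameters per image mode: concatenated images train with
# 0.07/0.07, single-gene images with 0.3/0.1
_MODE_HYPER = {
    "concat": (0.07, 0.07),
    "cytb": (0.3, 0.1),
    "coi": (0.3, 0.1),
}


def default_hyper(mode: str) -> tuple[float, float]:
    """(learning_rate, momentum) defaults for an image mode."""
    return _MODE_HYPER[mode]


@dataclass
class Ensemble:
    """Five trained networks sharing one teaching set and image mode."""

    mode: str
    members: list[MLPModel]
    teaching_set: list[str]
    ref: ReferenceLengths

    def __post_init__(self) -> None:
        for m in self.members:
            if m.label_order != self.teaching_set:
                raise ValueError("all members must share the teaching-set label order")


@dataclass(frozen=True)
class RecognitionReport:
    """Averaged activations for one query with threshold calls."""

    query_id: str
    mode: str
    averages: dict[str, float]
    threshold: float
    recognized: list[str] = field(default_factory=list)
    below_threshold_top: str | None = None

    @property
    def foreground(self) -> str | None:
        return self.recognized[0] if self.recognized else None

    @property
    def background(self) -> list[str]:
        return self.recognized[1:]

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "mode": self.mode,
            "threshold": self.threshold,
            "averages": self.averages,
            "recognized": self.recognized,
            "foreground": self.foreground,
            "background": self.background,
            "below_threshold_top": self.below_threshold_top,
        }


def teach_ensemble(
    panel: list[OrganismRecord],
    exclude: set[str] | None = None,
    mode: str = "concat",
    base_seed: int = 0,
    ref: ReferenceLengths | None = None,
    n_members: int = DEFAULT_MEMBERS,
    hyper: dict | None = None,
) -> Ensemble:
    """Teach an ensemble on the panel minus ``exclude`` (Latin names).

    Members use seeds ``base_seed .. base_seed+n_members-1``. Teaching-set
    order (= network output order) is alphabetical by Latin name. Any member
    failing to reach the RMSE target raises, naming its seed.
    """
    ref = ref or ReferenceLengths()
    exclude = exclude or set()
    teachers = sorted(
        (r for r in panel if r.latin_name not in exclude), key=lambda r: r.latin_name
    )
    if len(teachers) < 1:
        raise ValueError("teaching set is empty after exclusion")
    labels = [r.latin_name for r in teachers]
    images = [build_genetic_image(r, ref, mode) for r in teachers]
    samples = [img.bits.astype(float) for img in images]
    seen_bits: dict[bytes, str] = {}
    for label, img in zip(labels, images):
        key = img.bits.tobytes()
        if key in seen_bits:
            raise ValueError(
                f"identical {mode} teaching images for {seen_bits[key]!r} and "
                f"{label!r}; one-hot training cannot separate them"
            )
        seen_bits[key] = label
    k = len(teachers)
    targets = [np.eye(k)[i] for i in range(k)]

    lr, mom = default_hyper(mode)
    overrides = dict(hyper or {})
    members: list[MLPModel] = []
    for j in range(n_members):
        cfg = MLPConfig(
            n_inputs=samples[0].size,
            n_outputs=k,
            learning_rate=overrides.get("learning_rate", lr),
            momentum=overrides.get("momentum", mom),
            target_rmse=overrides.get("target_rmse", 0.01),
            max_epochs=overrides.get("max_epochs", 50_000),
            n_hidden=overrides.get("n_hidden"),
            seed=base_seed + j,
        )
        model = init_mlp(cfg, labels)
        trained, _log = train_online(model, samples, targets)
        members.append(trained)
    return Ensemble(mode=mode, members=members, teaching_set=labels, ref=ref)


def recognize(
    ensemble: Ensemble,
    query: GeneticImage,
    threshold: float = RECOGNITION_THRESHOLD,
) -> RecognitionReport:
    """Average the members' activations for a query and apply the threshold.

    ``recognized`` is sorted by descending average with a lexicographic
    tie-break on Latin name, so reports are fully deterministic.
    """
    if query.mode != ensemble.mode:
        raise ValueError(f"query mode {query.mode} != ensemble mode {ensemble.mode}")
    x = query.bits.astype(float)
    outs = np.stack([forward(m, x) for m in ensemble.members])
    avg = outs.mean(axis=0)
    averages = {org: float(a) for org, a in zip(ensemble.teaching_set, avg)}
    ranked = sorted(averages.items(), key=lambda kv: (-kv[1], kv[0]))
    recognized = [org for org, a in ranked if a >= threshold]
    below_top = ranked[0][0] if ranked and not recognized else None
    return RecognitionReport(
        query_id=query.organism_id,
        mode=ensemble.mode,
        averages=averages,
        threshold=threshold,
        recognized=recognized,
        below_threshold_top=below_top,
    )
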