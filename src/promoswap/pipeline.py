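"""End-to-end design glue: genome + annotation -> guide, arms, element."""

from __future__ import annotations

from dataclasses import dataclass

from .construct_design import ArmPair, ElementLayout, SyntheticElement, build_element, extract_arms
from .errors import DesignError
from .guide_design import GuideCandidate, GuideConfig, design_guide
from .sequence_model import GeneAnnotation, GenomeRef, OrientedLocus, orient_locus


@dataclass
class ConstructDesign:
    locus: OrientedLocus
    guide: GuideCandidate
    arms: ArmPair
    element: SyntheticElement


def design_construct(
    genome: GenomeRef,
    ann: GeneAnnotation,
    arm_len: int = 162,
    window: int = 500,
    cfg: GuideConfig | None = None,
    layout: ElementLayout | None = None,
) -> ConstructDesign:
    """Design one promoter-replacement construct for a gene.

    Arms are placed first so that guide selection can require the cut (and
    the protospacer) to fall inside the deleted promoter interval, which
    prevents the edited allele from being re-cut.
    """
    cfg = cfg or GuideConfig()
    layout = layout or ElementLayout(arm_len=arm_len)
    if layout.arm_len != arm_len:
        raise DesignError("layout arm_len disagrees with requested arm_len")
    locus = orient_locus(genome, ann, u=window, d=max(arm_len, 30))
    arms = extract_arms(locus, arm_len=arm_len, window=window)
    guide = design_guide(locus, genome, cfg, deleted_interval=arms.deleted_interval)
    element = build_element(guide, arms, layout)
    return ConstructDesign(locus, guide, arms, element)


def design_library(
    genome: GenomeRef,
    annotations: list[GeneAnnotation],
    arm_len: int = 162,
    window: int = 500,
    cfg: GuideConfig | None = None,
    layout: ElementLayout | None = None,
) -> tuple[dict[str, ConstructDesign], dict[str, str]]:
    """Design constructs for every annotated target.

    Returns (designs by gene_id, failures by gene_id with the reason).
    """
    designs: dict[str, ConstructDesign] = {}
    failures: dict[str, str] = {}
    for ann in annotations:
        try:
            designs[ann.gene_id] = design_construct(
                genome, ann, arm_len=arm_len, window=window, cfg=cfg, layout=layout
            )
        except DesignError as exc:
            failures[ann.gene_id] = str(exc)
    return designs, failures
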