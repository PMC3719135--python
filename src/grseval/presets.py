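"""Named scenario presets for both simulators.

The liability grid crosses three MAF patterns (all common 0.4, all rare 0.05,
alternating common/rare), equal vs. unequal effect sizes, and three
interaction strengths (negligible 0.0, moderate 0.2, strong 0.5), under two
causal-role scenarios: scenario 1 has four causal loci (main effects on all,
interaction between loci 3 and 4), scenario 2 keeps only loci 3 and 4 causal
with loci 1 and 2 as noise.  Six-locus follow-ups add a second two-way
interaction (``model37``) or a three-way interaction (``model38``).

Effect-size choices per pattern (equal / unequal): common 0.2 / (0.2, 0.5);
rare 0.8 / (0.2, 0.8); mixed common-rare 0.2 & 0.8 per the variant class.
These place total heritability well below 5%, in the detectable-but-hard
regime the study design targets.
"""

from __future__ import annotations

import itertools

from .datasets import LocusSpec
from .errors import ConfigurationError
from .ldsim import LDStructure, PenetranceModelSpec
from .liability import InteractionTerm, LiabilityModelSpec

__all__ = [
    "liability_presets",
    "scenario_presets",
    "ld_presets",
    "get_preset",
    "INTERACTION_LEVELS",
]

INTERACTION_LEVELS = {"noInteraction": 0.0, "moderate": 0.2, "strong": 0.5}

_MAF_PATTERNS = {
    "common": (0.4, 0.4, 0.4, 0.4),
    "rare": (0.05, 0.05, 0.05, 0.05),
    "mixed": (0.4, 0.05, 0.4, 0.05),  # loci 1 and 3 common, 2 and 4 rare
}

# effect size by variant class: common variants get small effects, rare
# variants larger ones, keeping per-locus heritability comparable
_EQUAL_ES = {0.4: 0.2, 0.05: 0.8}
_UNEQUAL_ES = {0.4: (0.2, 0.5), 0.05: (0.2, 0.8)}


def _main_effects(mafs: tuple[float, ...], equal: bool) -> tuple[float, ...]:
    if equal:
        return tuple(_EQUAL_ES[m] for m in mafs)
    out = []
    toggles: dict[float, int] = {}
    for m in mafs:
        i = toggles.get(m, 0)
        out.append(_UNEQUAL_ES[m][i % 2])
        toggles[m] = i + 1
    return tuple(out)


def _loci(mafs: tuple[float, ...]) -> tuple[LocusSpec, ...]:
    return tuple(LocusSpec(locus_id=f"SNP{i + 1}", maf=m) for i, m in enumerate(mafs))


def liability_presets() -> dict[str, LiabilityModelSpec]:
    """The full named grid of liability-threshold scenarios."""
    presets: dict[str, LiabilityModelSpec] = {}
    for scen, (pattern, mafs), es_name, (int_name, coef) in itertools.product(
        ("scenario1", "scenario2"),
        _MAF_PATTERNS.items(),
        ("equalES", "unequalES"),
        INTERACTION_LEVELS.items(),
    ):
        me = list(_main_effects(mafs, es_name == "equalES"))
        if scen == "scenario2":  # loci 1 and 2 are pure noise
            me[0] = me[1] = 0.0
        name = f"{scen}/{pattern}/{es_name}/{int_name}"
        presets[name] = LiabilityModelSpec(
            loci=_loci(mafs),
            main_effects=tuple(me),
            interactions=(InteractionTerm(loci=(2, 3), coefficient=coef),),
        )

    # null model for type-I-error studies
    presets["null"] = LiabilityModelSpec(
        loci=_loci(_MAF_PATTERNS["common"]),
        main_effects=(0.0, 0.0, 0.0, 0.0),
        interactions=(InteractionTerm(loci=(2, 3), coefficient=0.0),),
    )

    # six-locus follow-ups (all common): two two-way interactions, or one
    # three-way interaction, at the moderate strength level
    six = tuple(LocusSpec(locus_id=f"SNP{i + 1}", maf=0.4) for i in range(6))
    presets["model37-style"] = LiabilityModelSpec(
        loci=six,
        main_effects=(0.2,) * 6,
        interactions=(
            InteractionTerm(loci=(2, 3), coefficient=0.2),
            InteractionTerm(loci=(4, 5), coefficient=0.2),
        ),
    )
    presets["model38-style"] = LiabilityModelSpec(
        loci=six,
        main_effects=(0.2,) * 6,
        interactions=(InteractionTerm(loci=(2, 3, 4), coefficient=0.2),),
    )
    return presets


# spec'd operation name
def scenario_presets() -> dict[str, LiabilityModelSpec]:
    return liability_presets()


_LD_MAF_PATTERNS = {
    "common": (0.4, 0.4),
    "rare": (0.05, 0.05),
    "common-rare": (0.4, 0.05),
    "rare-common": (0.05, 0.4),
}
_LD_RR = {"equalRR": (1.5, 1.5), "unequalRR": (1.25, 1.75)}


def ld_presets() -> dict[str, tuple[PenetranceModelSpec, LDStructure]]:
    """Penetrance-model scenarios crossed with strong/weak LD structures.

    The marker (locus 3) MAF matches causal locus 2; strong LD places 0.8
    conditional mass on the matching genotype.
    """
    presets: dict[str, tuple[PenetranceModelSpec, LDStructure]] = {}
    for (pat, mafs), (rr_name, rrs), mode in itertools.product(
        _LD_MAF_PATTERNS.items(), _LD_RR.items(), ("strong", "weak")
    ):
        spec = PenetranceModelSpec(
            baseline_penetrance=0.1,
            relative_risks=rrs,
            mafs=(mafs[0], mafs[1], mafs[1]),
        )
        ld = LDStructure.strong(mafs[1]) if mode == "strong" else LDStructure.weak(mafs[1])
        presets[f"ld/{pat}/{rr_name}/{mode}"] = (spec, ld)
    return presets


def get_preset(name: str):
    """Resolve a preset by name; unknown names list what is available."""
    lia = liability_presets()
    if name in lia:
        return lia[name]
    ld = ld_presets()
    if name in ld:
        return ld[name]
    available = sorted(lia) + sorted(ld)
    raise ConfigurationError(
        f"unknown preset {name!r}; available presets:\n  " + "\n  ".join(available)
    )
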