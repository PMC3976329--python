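"""Reproductive-lifespan effect-direction classes.

A variant that moves age at menarche and age at natural menopause in the
same direction shifts the whole reproductive window earlier or later
(``left_shift`` / ``right_shift``); opposite-direction effects lengthen or
shorten it (``lifespan_increase`` / ``lifespan_decrease``).  Both effects
must be expressed on the same effect allele before classification.
"""

from __future__ import annotations

import enum


class EffectClass(enum.Enum):
    """Joint direction of a variant's effect on menarche and menopause age."""

    RIGHT_SHIFT = "right_shift"
    LEFT_SHIFT = "left_shift"
    LIFESPAN_INCREASE = "lifespan_increase"
    LIFESPAN_DECREASE = "lifespan_decrease"


class UnclassifiableEffectError(ValueError):
    """Raised when either trait effect is zero (direction undefined)."""


def classify_signs(menarche_effect: float, menopause_effect: float) -> EffectClass:
    """Classify a (menarche, menopause) effect pair by sign.

    Rules: both positive -> the menarche-increasing allele also increases
    menopause age, i.e. the window shifts right; both negative -> left shift;
    menarche-decreasing with menopause-increasing -> longer reproductive
    lifespan; the reverse -> shorter.

    Parameters are any signed effect sizes (betas or Z scores) aligned to a
    single shared effect allele; only their signs are used.
    """
    if menarche_effect == 0 or menopause_effect == 0:
        raise UnclassifiableEffectError(
            "effect direction undefined: zero effect on at least one trait"
        )
    if menarche_effect > 0 and menopause_effect > 0:
        return EffectClass.RIGHT_SHIFT
    if menarche_effect < 0 and menopause_effect < 0:
        return EffectClass.LEFT_SHIFT
    if menarche_effect < 0:
        return EffectClass.LIFESPAN_INCREASE
    return EffectClass.LIFESPAN_DECREASE
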