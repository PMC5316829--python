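"""Small closed-form geometric models."""

from __future__ import annotations

__all__ = ["cylinder_volume_fold_change"]


def cylinder_volume_fold_change(diameter_fold: float, length_fold: float = 1.0) -> float:
    """Volume ratio of a cylinder whose diameter scales by ``diameter_fold``.

    At constant length, volume ~ diameter^2, so a tenfold diameter increase
    gives a 100-fold luminal volume increase.
    """
    if diameter_fold <= 0 or length_fold <= 0:
        raise ValueError("scale factors must be positive")
    return diameter_fold ** 2 * length_fold
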