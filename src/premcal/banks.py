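"""Published item bank for the physical-health care-planning experience measure.

The 19 retained items with their partial-credit threshold parameters (theta
metric) and the uniform 0-1-1-2-2 raw-to-scored category map, as printed in
the development study's final item table.  Items are ordered by ascending
second threshold, matching the printed table; ``item_id`` keeps the item's
number in the original 67-item candidate pool.
"""

from __future__ import annotations

from .data_io import Item, ItemBank

__all__ = ["EQUIP_PH_BANK", "equip_ph_bank"]

_SCORING = (0, 1, 1, 2, 2)

_ROWS = [
    ("50", "My care planning team ask about my existing physical health conditions.", -1.20, 0.12),
    ("24", "The physical health information in my care plan is personalised.", -1.92, 0.20),
    ("53", "My care planning team encourage me to take responsibility for my physical health care planning.", -2.01, 0.27),
    ("37", "My opinion on my physical health is valued by my care planning team.", -2.03, 0.38),
    ("4", "I know who reads the physical health information contained within my care plan", -1.02, 0.43),
    ("55", "My care planning team offer practical advice about my physical health.", -1.42, 0.51),
    ("13", "My care plan gives details of my physical health history.", -1.16, 0.52),
    ("15", "My thoughts about my physical health are included in my care plan.", -0.62, 0.76),
    ("52", "I experience continuity of care for the treatment of both my physical health conditions and mental health conditions.", -0.68, 0.77),
    ("22", "The physical health information in my care plan is helpful.", -1.61, 0.83),
    ("16", "Physical health reviews are carried out in a timely manner.", -0.53, 0.86),
    ("62", "My care planning team have a good understanding of my fears about future physical health conditions.", -0.77, 0.92),
    ("56", "My care planning team have the time they need to talk to me about physical health concerns.", -1.18, 0.94),
    ("44", "The content of my physical health care plan is responsive to changes in my circumstances.", -1.14, 1.06),
    ("27", "Information in my care plan has helped me to maintain my physical health.", -0.63, 1.08),
    ("41", "I was asked what I wanted in the physical health information in my care plan.", -0.25, 1.13),
    ("60", "The care plan adequately addresses any side effects I experience from my medication.", -1.22, 1.13),
    ("46", "I have had the opportunity to invite all the relevant people to care planning meetings related to my physical health.", -0.55, 1.27),
    ("51", "My care planning team makes sure my mental health is not prioritised over my physical health.", -1.15, 1.51),
]


def equip_ph_bank() -> ItemBank:
    """Return a fresh copy of the published 19-item calibrated bank."""
    return ItemBank(
        [Item(item_id=i, label=lab, deltas=(d1, d2), scoring_map=_SCORING) for i, lab, d1, d2 in _ROWS]
    )


EQUIP_PH_BANK: ItemBank = equip_ph_bank()
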