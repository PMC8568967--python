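"""Decide whether a parasitoid can reach a flower's nectar.

Builds two wasps and three flowers, runs the geometric decision tree and
prints the verdicts and the accessible percent cover of a tiny community.
"""

from nectarweb import (
    FlowerMorphology,
    InsectMorphology,
    accessible_cover,
    nectar_accessible,
)

# lengths in mm; activity / flowering windows in day-of-year
small_wasp = InsectMorphology("small_wasp", head_width=0.5, proboscis_length=0.25,
                              proboscis_width=0.05, activity_start=120, activity_end=170)
large_wasp = InsectMorphology("large_wasp", head_width=1.6, proboscis_length=2.0,
                              proboscis_width=0.12, activity_start=100, activity_end=150)

flowers = {
    "open_daisy": FlowerMorphology("open_daisy", opening_width=4.0, corolla_height=0.5,
                                   nectar_depth=0.3, flower_start=110, flower_end=190),
    "deep_tube": FlowerMorphology("deep_tube", opening_width=0.8, corolla_height=3.0,
                                  nectar_depth=2.0, tube_diameter=0.1,
                                  flower_start=130, flower_end=200),
    "vetch_efn": FlowerMorphology("vetch_efn", nectar_type="extrafloral",
                                  flower_start=90, flower_end=160),
}

for wasp in (small_wasp, large_wasp):
    for name, fl in flowers.items():
        v = nectar_accessible(wasp, fl)
        print(f"{wasp.taxon:11s} x {name:10s}: accessible={v.accessible!s:5s} ({v.reason.value})")

covers = {"open_daisy": 30.0, "deep_tube": 25.0, "vetch_efn": 10.0}
for wasp in (small_wasp, large_wasp):
    c = accessible_cover(covers, flowers, wasp)
    print(f"{wasp.taxon}: {c:.0f}% of plant cover provides available+accessible nectar")
# The percent cover is the mass-ratio covariate used downstream: how much of
# the community a given parasitoid can actually feed on.
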