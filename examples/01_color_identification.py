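"""Impartial color categorization of a taxon's iris images.

Builds a small synthetic taxon whose images mix a brown morph and a
gray morph, then runs the survey: per image mean RGB -> hex -> named
color -> basic category, per-taxon frequencies and the most-common
color set under the predominance thresholds.
"""

import irisphylo as ip

table = ip.make_color_table()

# a taxon sampled 20 times: 10 brown-eyed, 9 gray-eyed, 1 green-eyed individuals
brown = ip.gen_iris(400, [((101, 67, 33), 1.0, "iris")], noise_sd=4, seed=1).pixels
gray = ip.gen_iris(400, [((128, 128, 128), 1.0, "iris")], noise_sd=4, seed=2).pixels
green = ip.gen_iris(400, [((46, 111, 64), 1.0, "iris")], noise_sd=4, seed=3).pixels
images = (
    {f"brown_{i}": brown for i in range(10)}
    | {f"gray_{i}": gray for i in range(9)}
    | {"green_0": green}
)

survey = ip.survey_taxon("synthetic_felid", images, table)

first = survey.image_records[0]
print(f"example image: mean RGB {first['rgb']} -> {first['hex']} -> "
      f"{first['name']!r} -> category {first['category']!r}")
print(f"category frequencies: {survey.frequencies}")
print(f"observed colors:      {sorted(survey.observed)}")
print(f"most common colors:   {sorted(survey.most_common)}")
print()
print("Both brown and gray clear the >40% two-color threshold, so this taxon")
print("is scored as polymorphic (brown + gray); the single green image is a")
print("rare morph recorded as observed but not among the most common colors.")
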