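# Synthetic default point tables for the 11-sub-index additive dementia risk
# index. The published per-category points are not reproduced here; these
# synthetic values preserve the published raw range (-13 .. +19, i.e. 0..32
# after the +13 shift), the sign convention (protective factors score
# negative), and monotone ordering of risk within each sub-index.
shift_constant: 13
min_raw: -13
max_raw: 19
sub_indices:
  age_sex:
    # scored on age band; the cohort enters at 60-64
    categories: ["60_64", "65_69", "70_plus"]
    breaks: [65, 70]          # upper bounds of the first two bands (years)
    points: {"60_64": 0, "65_69": 1, "70_plus": 2}
  education:
    categories: ["low", "mid", "high"]
    breaks: [9, 13]           # years of education
    points: {"low": 2, "mid": 0, "high": -3}
  alcohol:
    # categorisation is sex-specific (see categorize_alcohol); light-moderate
    # drinking is protective
    categories: ["abstainer", "light_moderate", "heavy"]
    points: {"abstainer": 0, "light_moderate": -3, "heavy": 2}
  smoking:
    categories: ["never", "past", "current"]
    points: {"never": 0, "past": 1, "current": 4}
  diabetes:
    categories: ["no", "yes"]
    points: {"no": 0, "yes": 3}
  depression:
    # PHQ-9 > 10
    categories: ["no", "yes"]
    points: {"no": 0, "yes": 2}
  tbi:
    # traumatic brain injury with loss of consciousness
    categories: ["no", "yes"]
    points: {"no": 0, "yes": 2}
  bmi:
    categories: ["normal", "overweight", "obese"]
    breaks: [25, 30]          # kg/m^2
    points: {"normal": 0, "overweight": 1, "obese": 2}
  physical_activity:
    # weighted hours/week: mild*1 + moderate*2 + vigorous*3
    categories: ["low", "mid", "high"]
    breaks: [2, 4]
    points: {"low": 0, "mid": -1, "high": -2}
  social_engagement:
    # five-domain composite (fifth domain pro-rata mean of the four observed)
    categories: ["low", "mid", "high"]
    breaks: [3, 6]
    points: {"low": 0, "mid": -1, "high": -2}
  cognitive_activity:
    # number of cognitively stimulating activities, 0-4
    categories: ["low", "mid", "high"]
    breaks: [2, 4]
    points: {"low": 0, "mid": -1, "high": -3}
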