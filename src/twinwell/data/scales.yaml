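# Default scale definitions for the measured variables.
#
# Reverse-keyed items are explicit configuration: negatively worded items
# (relationship problems; being taken advantage of) are reversed by default.
# Scoring is `sum` unless noted; all missingness is complete-case (any
# missing item yields a missing score).
swls:
  items: [swls_1, swls_2, swls_3, swls_4, swls_5]
  response_min: 1
  response_max: 7
  reverse_items: []
  scoring: sum
rss:
  items: [rss_happy, rss_problems, rss_understood, rss_satisfied, rss_children]
  response_min: 1
  response_max: 6
  reverse_items: [rss_problems]
  scoring: sum
ecr_anxiety:
  items: [ecr_anx_1, ecr_anx_2, ecr_anx_3, ecr_anx_4, ecr_anx_5, ecr_anx_6]
  response_min: 1
  response_max: 7
  reverse_items: []
  scoring: sum
ecr_avoidance:
  items: [ecr_avo_1, ecr_avo_2, ecr_avo_3, ecr_avo_4, ecr_avo_5, ecr_avo_6]
  response_min: 1
  response_max: 7
  reverse_items: []
  scoring: sum
ucla_loneliness:
  items: [ucla_isolated, ucla_lack_company, ucla_left_out]
  response_min: 1
  response_max: 5
  reverse_items: []
  scoring: sum
trust:
  items: [trust_people, trust_advantage, trust_helpful]
  response_min: 0
  response_max: 10
  reverse_items: [trust_advantage]
  scoring: sum
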