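# Default 12-subject synthetic cohort (4 children, 4 younger adults, 4 older
# adults).  State-variable targets fall in the printed per-group ranges for
# TBS, intake and days of stores.  Exchange turnovers follow the human
# retinol literature (plasma transit of a few hours, extensive recycling):
# compartment 7 is a small fast-exchanging extravascular pool, compartment 6
# the large slow store whose return time grows with vitamin A status (about
# 8 d in the smallest child to 45 d in the highest-TBS older adult), so
# crossover time increases with TBS across the cohort.  Exchange splits were
# chosen by an information (design-FSD) criterion: all six adjustable
# coefficients identifiable from a full-length 5%-noise study, and TBS
# well-determined from 114 d of data.  These are synthetic, range-matched
# stand-ins, not any study's assigned values.
# tbs: umol; intake: umol/d; m5: umol; store_ratio: M6/M7;
# l_6_5, l_7_5: /d (plasma -> store exchange).
subjects:
  - {id: C1,  group: child,         age: 6 mo, tbs: 31,   intake: 0.53, m5: 0.7, store_ratio: 8,     l_6_5: 4.921, l_7_5: 5.905}
  - {id: C2,  group: child,         age: 2 y,  tbs: 180,  intake: 1.5,  m5: 1.2, store_ratio: 21.5,  l_6_5: 11.94, l_7_5: 8}
  - {id: C3,  group: child,         age: 4 y,  tbs: 520,  intake: 2.6,  m5: 1.8, store_ratio: 42.33, l_6_5: 17.64, l_7_5: 8}
  - {id: C4,  group: child,         age: 5 y,  tbs: 1100, intake: 4.3,  m5: 2.5, store_ratio: 43,    l_6_5: 21.5,  l_7_5: 8}
  - {id: Y5,  group: younger_adult, age: 22 y, tbs: 210,  intake: 1.3,  m5: 4.5, store_ratio: 6.667, l_6_5: 4.058, l_7_5: 4.87}
  - {id: Y6,  group: younger_adult, age: 27 y, tbs: 430,  intake: 2.2,  m5: 5.5, store_ratio: 9.333, l_6_5: 5.044, l_7_5: 6.053}
  - {id: Y7,  group: younger_adult, age: 31 y, tbs: 700,  intake: 3.0,  m5: 6.5, store_ratio: 12,    l_6_5: 5.523, l_7_5: 6.627}
  - {id: Y8,  group: younger_adult, age: 35 y, tbs: 1030, intake: 3.9,  m5: 7.5, store_ratio: 9.167, l_6_5: 5.628, l_7_5: 6.754}
  - {id: O9,  group: older_adult,   age: 45 y, tbs: 460,  intake: 1.9,  m5: 5.0, store_ratio: 9.333, l_6_5: 5.935, l_7_5: 7.123}
  - {id: O10, group: older_adult,   age: 50 y, tbs: 900,  intake: 2.8,  m5: 6.0, store_ratio: 8.375, l_6_5: 6.7,   l_7_5: 8}
  - {id: O11, group: older_adult,   age: 55 y, tbs: 1700, intake: 3.1,  m5: 6.5, store_ratio: 15.35, l_6_5: 8.769, l_7_5: 8}
  - {id: O12, group: older_adult,   age: 60 y, tbs: 3000, intake: 3.2,  m5: 7.0, store_ratio: 72,    l_6_5: 9.393, l_7_5: 4.697}
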