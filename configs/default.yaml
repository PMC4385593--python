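# Default study conditions: 50 users observed for one year (363 days =
# 121 tumbling 3-day windows per user).  Any omitted key falls back to the
# package default; run `elderwatch pipeline --config configs/default.yaml`.
n_users: 50
start_date: 2014-01-01
end_date: 2014-12-29
seed: 12345

demographics:
  age_mean: 75.0
  age_sd: 10.0
  marital_fractions:
    married: 0.30
    widowed: 0.50
    single: 0.10
    divorced: 0.08
    cohabitation: 0.02

profiles:
  fractions: {low: 0.20, average: 0.50, high: 0.30}
  session_rate: {low: 0.35, average: 1.2, high: 3.0}
  duration_median: {low: 55.0, average: 40.0, high: 30.0}
  marathon_prob: {low: 0.10, average: 0.07, high: 0.05}

errors:
  temperature_rate: 0.02
  humidity_rate: 0.02
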