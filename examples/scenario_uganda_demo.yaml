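# Demonstration national scale-up scenario (synthetic inputs of
# published order of magnitude; replace with national data for real use).
country: Uganda
che: 4330000000.0
gdp: 114300000000.0
profiles:
  HIV:
    prevalent_count: 1400000
    proportion: 0.58
    coverage_current: 0.8
    coverage_target: 0.95
    mean_monthly_cost:
      integrated: 14.0
      standard: 14.6
    mean_monthly_cost_ci:
      integrated:
      - 12.6
      - 15.400000000000002
      standard:
      - 13.14
      - 16.060000000000002
    proportion_ci:
    - 0.522
    - 0.638
  HTN:
    prevalent_count: 3500000
    proportion: 0.45
    coverage_current: 0.55
    coverage_target: 0.8
    mean_monthly_cost:
      integrated: 8.9
      standard: 9.1
    mean_monthly_cost_ci:
      integrated:
      - 8.01
      - 9.790000000000001
      standard:
      - 8.19
      - 10.01
    proportion_ci:
    - 0.405
    - 0.49500000000000005
  DM:
    prevalent_count: 800000
    proportion: 0.55
    coverage_current: 0.55
    coverage_target: 0.8
    mean_monthly_cost:
      integrated: 7.0
      standard: 5.9
    mean_monthly_cost_ci:
      integrated:
      - 6.3
      - 7.700000000000001
      standard:
      - 5.3100000000000005
      - 6.490000000000001
    proportion_ci:
    - 0.49500000000000005
    - 0.6050000000000001
  HIV+HTN:
    prevalent_count: 1400000
    proportion: 0.09
    coverage_current: 0.8
    coverage_target: 0.95
    mean_monthly_cost:
      integrated: 16.4
      standard: 24.4
    mean_monthly_cost_ci:
      integrated:
      - 14.76
      - 18.04
      standard:
      - 21.96
      - 26.84
    proportion_ci:
    - 0.081
    - 0.099
  HIV+DM:
    prevalent_count: 1400000
    proportion: 0.012
    coverage_current: 0.8
    coverage_target: 0.95
    mean_monthly_cost:
      integrated: 16.3
      standard: 20.4
    mean_monthly_cost_ci:
      integrated:
      - 14.670000000000002
      - 17.930000000000003
      standard:
      - 18.36
      - 22.44
    proportion_ci:
    - 0.0108
    - 0.013200000000000002
  HTN+DM:
    prevalent_count: 3500000
    proportion: 0.075
    coverage_current: 0.55
    coverage_target: 0.8
    mean_monthly_cost:
      integrated: 9.4
      standard: 16.4
    mean_monthly_cost_ci:
      integrated:
      - 8.46
      - 10.340000000000002
      standard:
      - 14.76
      - 18.04
    proportion_ci:
    - 0.0675
    - 0.0825
  HIV+HTN+DM:
    prevalent_count: 1400000
    proportion: 0.02
    coverage_current: 0.8
    coverage_target: 0.95
    mean_monthly_cost:
      integrated: 15.7
      standard: 25.8
    mean_monthly_cost_ci:
      integrated:
      - 14.129999999999999
      - 17.27
      standard:
      - 23.220000000000002
      - 28.380000000000003
    proportion_ci:
    - 0.018000000000000002
    - 0.022000000000000002
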