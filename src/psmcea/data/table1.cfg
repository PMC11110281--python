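# Published model inputs: ivosidenib vs mFOLFOX vs 5-FU/LV for previously
# treated IDH1-mutant advanced intrahepatic cholangiocarcinoma (Taiwan NHIA
# perspective). Costs in 2022 NT$; survival parameters are log-normal
# (meanlog, sdlog) on a time scale of months. DSA ranges: survival parameters
# at their 95% CI, others +/-25% unless noted. PSA: normal = (mean, se),
# gamma = (shape, rate), beta = (alpha, beta), uniform = (min, max).

parameters:
  os_ivosidenib_meanlog:
    {value: 2.2773, dsa: [2.0715, 2.4831],
     psa: {family: normal, params: [2.2773, 0.105]}, units: log-months}
  os_ivosidenib_sdlog:
    {value: 1.13, dsa: [0.9665, 1.2935],
     psa: {family: normal, params: [1.13, 0.0834]}, units: log-months}
  os_mfolfox_meanlog:
    {value: 1.8419, dsa: [1.6522, 2.0316],
     psa: {family: normal, params: [1.8419, 0.0968]}, units: log-months}
  os_mfolfox_sdlog:
    {value: 0.8586, dsa: [0.7187, 0.9985],
     psa: {family: normal, params: [0.8586, 0.0714]}, units: log-months}
  os_5fulv_meanlog:
    {value: 1.7813, dsa: [1.6080, 1.9546],
     psa: {family: normal, params: [1.7813, 0.0884]}, units: log-months}
  os_5fulv_sdlog:
    {value: 0.792, dsa: [0.6601, 0.9239],
     psa: {family: normal, params: [0.792, 0.0673]}, units: log-months}
  pfs_ivosidenib_meanlog:
    {value: 1.199, dsa: [0.9893, 1.4087],
     psa: {family: normal, params: [1.199, 0.107]}, units: log-months}
  pfs_ivosidenib_sdlog:
    {value: 1.049, dsa: [0.8785, 1.2195],
     psa: {family: normal, params: [1.049, 0.087]}, units: log-months}
  pfs_mfolfox_meanlog:
    {value: 1.4414, dsa: [1.2809, 1.6019],
     psa: {family: normal, params: [1.4414, 0.0819]}, units: log-months}
  pfs_mfolfox_sdlog:
    {value: 0.7361, dsa: [0.6205, 0.8517],
     psa: {family: normal, params: [0.7361, 0.059]}, units: log-months}
  pfs_5fulv_meanlog:
    {value: 0.8171, dsa: [0.5935, 1.0407],
     psa: {family: normal, params: [0.8171, 0.1141]}, units: log-months}
  pfs_5fulv_sdlog:
    {value: 1.0347, dsa: [0.8705, 1.1989],
     psa: {family: normal, params: [1.0347, 0.0838]}, units: log-months}

  exchange_rate:
    {value: 29.81, psa: {family: uniform, params: [27.93, 31.01]},
     units: NT$ per USD}
  # hypothesised price (NT$10,402 per 500 mg daily); DSA range is an
  # assumption, PSA variation enters through the exchange rate only
  med_cost_ivosidenib:
    {value: 3744552, dsa: [2808414, 4680690], units: NT$/year}
  med_cost_mfolfox: {value: 132708, units: NT$/year}
  med_cost_5fulv: {value: 26124, units: NT$/year}

  nonmed_cost_ivosidenib:
    {value: 291576, dsa: [218682, 364470],
     psa: {family: gamma, params: [16.56, 0.00006]}, units: NT$/year}
  nonmed_cost_chemotherapy:
    {value: 856986, dsa: [642740, 1071233],
     psa: {family: gamma, params: [59.94, 0.00007]}, units: NT$/year}
  supportive_care_cost:
    {value: 497710, dsa: [373283, 622138],
     psa: {family: gamma, params: [69.3, 0.00014]}, units: NT$/year}

  utility_pf:
    {value: 0.76, dsa: [0.57, 0.95],
     psa: {family: beta, params: [4.7, 1.5]}, units: utility}
  utility_pp:
    {value: 0.68, dsa: [0.51, 0.85],
     psa: {family: beta, params: [29, 13.6]}, units: utility}
  disutility_iv:
    {value: 0.025, dsa: [0.01875, 0.03125], units: utility}
  disutility_ae:
    {value: 0.16, dsa: [0.12, 0.2],
     psa: {family: beta, params: [36, 193]}, units: utility}

  discount_rate: {value: 0.03, dsa: [0.0, 0.05], units: per-year}
  conversion_factor:
    {value: 0.9, psa: {family: uniform, params: [0.8, 1.0]},
     units: dimensionless}

settings:
  u_pf: utility_pf
  u_pp: utility_pp
  d_ae: disutility_ae
  d_iv: disutility_iv
  supportive_cost_per_year: supportive_care_cost
  discount_rate_per_year: discount_rate
  wtp_per_qaly: 2925582        # 3x 2022 GDP per capita
  horizon_years: 10
  cycle_length_years: 0.0833333333333333  # 1-month cycles
  conversion_factor: conversion_factor
  exchange_rate: exchange_rate

strategies:
  - name: ivosidenib
    route: oral
    ae_rate_per_cycle: 0.192
    med_cost_per_year: med_cost_ivosidenib
    nonmed_cost_per_year: nonmed_cost_ivosidenib
    price_from_exchange: true
    os:
      family: lognormal
      params: [os_ivosidenib_meanlog, os_ivosidenib_sdlog]
      se: [0.105, 0.0834]
    pfs:
      family: lognormal
      params: [pfs_ivosidenib_meanlog, pfs_ivosidenib_sdlog]
      se: [0.107, 0.087]
  - name: mFOLFOX
    route: intravenous
    ae_rate_per_cycle: 0.048
    med_cost_per_year: med_cost_mfolfox
    nonmed_cost_per_year: nonmed_cost_chemotherapy
    os:
      family: lognormal
      params: [os_mfolfox_meanlog, os_mfolfox_sdlog]
      se: [0.0968, 0.0714]
    pfs:
      family: lognormal
      params: [pfs_mfolfox_meanlog, pfs_mfolfox_sdlog]
      se: [0.0819, 0.059]
  - name: 5-FU/LV
    route: intravenous
    ae_rate_per_cycle: 0.013
    med_cost_per_year: med_cost_5fulv
    nonmed_cost_per_year: nonmed_cost_chemotherapy
    os:
      family: lognormal
      params: [os_5fulv_meanlog, os_5fulv_sdlog]
      se: [0.0884, 0.0673]
    pfs:
      family: lognormal
      params: [pfs_5fulv_meanlog, pfs_5fulv_sdlog]
      se: [0.1141, 0.0838]

psa_iterations: 1000
rng_seed: 20220101
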