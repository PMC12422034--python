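# Published national annual provider cost totals at current service coverage
# (2021 international dollars), by condition profile and care model, for
# Uganda and Tanzania, with the published arm-level budget-impact shares.
# Used to reconcile the aggregation arithmetic against the published report;
# printed rows carry rounding, so recomputed differences can deviate from
# printed difference cells by 1 Int$ (and the Tanzania standard grand total
# by 2 Int$).
Uganda:
  profile_totals:
    HIV: {integrated: 668995477, standard: 698801557}
    HTN: {integrated: 347416601, standard: 354755964}
    DM: {integrated: 61292465, standard: 51949839}
    HIV+HTN: {integrated: 139322728, standard: 207122763}
    HIV+DM: {integrated: 17929185, standard: 22435573}
    HTN+DM: {integrated: 148242221, standard: 258103172}
    HIV+HTN+DM: {integrated: 28812121, standard: 47366642}
  printed_differences:
    HIV: -29806079
    HTN: -7339363
    DM: 9342627
    HIV+HTN: -67800034
    HIV+DM: -4506389
    HTN+DM: -109860952
    HIV+HTN+DM: -18554521
  printed_grand_total: {integrated: 1412010798, standard: 1640535510, difference: -228524712}
  printed_pct_gdp: {integrated: 1.20, standard: 1.40, difference: -0.20}
  printed_pct_che: {integrated: 32.60, standard: 37.90, difference: -5.30}
Tanzania:
  profile_totals:
    HIV: {integrated: 744234202, standard: 738480466}
    HTN: {integrated: 140432057, standard: 124044720}
    DM: {integrated: 169257387, standard: 143454269}
    HIV+HTN: {integrated: 157440559, standard: 183461692}
    HIV+DM: {integrated: 30088514, standard: 34742322}
    HTN+DM: {integrated: 275251488, standard: 355161469}
    HIV+HTN+DM: {integrated: 33546797, standard: 42952128}
  printed_differences:
    HIV: 5753736
    HTN: 16387337
    DM: 25803119
    HIV+HTN: -26021133
    HIV+DM: -4653808
    HTN+DM: -79909981
    HIV+HTN+DM: -9405330
  printed_grand_total: {integrated: 1550251004, standard: 1622297064, difference: -72046061}
  printed_pct_gdp: {integrated: 0.89, standard: 0.93, difference: -0.04}
  printed_pct_che: {integrated: 23.13, standard: 24.20, difference: -1.07}
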