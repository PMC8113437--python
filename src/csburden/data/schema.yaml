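# Column schemas for the delimited-text layouts read and written by
# csburden.ingest.  All files are plain CSV (configurable separator).

supplementary:
  description: >
    Analysis-ready rows, one animal sample per row, with the decay-corrected
    ln total radiocesium already computed.
  columns:
    species:      "animal species; one of the accepted labels (boar / wild boar / black bear / ...)"
    T:            "collection time in decimal years since 2011-03-11 (365.25 days/year)"
    LnCs_c:       "ln of total radiocesium activity concentration (Bq/kg), corrected to collection time"
    district:     "district of Fukushima Prefecture where the animal was taken"
    municipality: "municipality within the district"
    below_detection: "(optional) boolean; rows marked true are excluded and counted"

raw:
  description: >
    Monitoring-style export with per-isotope activities at the measurement
    date.  LnCs_c is derived by back-correcting each isotope for physical
    decay over the collection-to-measurement delay.
  columns:
    species:          "animal species label"
    collection_date:  "date the animal was taken; ISO 8601 (YYYY-MM-DD) or YYYY/MM/DD"
    measurement_date: "date the activity was measured; same formats; must be >= collection_date"
    cs134:            "134Cs activity (Bq/kg) at measurement date; 'ND' / '<x' marks below detection"
    cs137:            "137Cs activity (Bq/kg) at measurement date; 'ND' / '<x' marks below detection"
    district:         "district label"
    municipality:     "municipality label"

analysis:
  description: "Analysis-ready table written by csburden (write_analysis_table)."
  columns:
    species:           "canonical species label: boar | black_bear"
    t:                 "years since the accident at collection (365.25 days/year)"
    ln_cs_c:           "decay-corrected ln total radiocesium (ln Bq/kg)"
    district:          "district label"
    municipality:      "municipality label"
    collection_date:   "collection date (blank for supplementary-dialect input)"
    measurement_date:  "measurement date (blank for supplementary-dialect input)"
    cs134:             "134Cs activity at measurement date (Bq/kg), if available"
    cs137:             "137Cs activity at measurement date (Bq/kg), if available"
    cs_total_reported: "total activity at measurement date (Bq/kg), if available"
    below_detection:   "always false in the analysis set"

chernobyl:
  description: >
    Zone/year summary rows for the Chernobyl weighted-regression arm.
  columns:
    Zone:       "Alienation | Permanent_control | Periodic_control"
    Time:       "years since the 1986 accident"
    N:          "number of animals summarised in the cell"
    LnMeanCs:   "ln of the mean 137Cs level in muscle (Bq/kg)"
    LnMinCs:    "ln of the minimum 137Cs level"
    LnMaxCs:    "ln of the maximum 137Cs level"
    LnMeanCs_c: "LnMeanCs minus ln of decay-corrected land contamination (Bq/m^2)"
    Weight:     "(optional) regression weight; recomputed as N/(LnMaxCs-LnMinCs)^2, mean-normalised"
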