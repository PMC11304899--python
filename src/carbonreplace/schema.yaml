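# Machine-readable schema for the delimited-text inventory interchange format.
# All files are UTF-8 CSV with a header row. Species codes are opaque strings.
tables:
  plots:
    file: plots.csv
    columns:
      plot_id: {dtype: str, doc: opaque plot key}
      latitude: {dtype: float, units: decimal degrees}
      longitude: {dtype: float, units: decimal degrees}
      elevation: {dtype: float, units: m}
      time1: {dtype: float, units: decimal year of first measurement}
      time2: {dtype: float, units: decimal year of second measurement}
      interval_years: {dtype: float, units: years, doc: "time2 - time1, must be > 0"}
      mat_c: {dtype: float, units: deg C, doc: 30-year mean annual temperature}
      map_mm: {dtype: float, units: mm, doc: 30-year mean annual precipitation}
      vpd_hpa: {dtype: float, units: hPa, doc: 30-year mean vapor pressure deficit}
  subplots:
    file: subplots.csv
    columns:
      plot_id: {dtype: str}
      subplot: {dtype: int, doc: "subplot number 1-4; exactly four per plot"}
      ri_surveyed_time1: {dtype: bool, doc: regeneration-indicator seedling survey done at time 1}
      ri_surveyed_time2: {dtype: bool}
  conditions:
    file: conditions.csv
    columns:
      condition_id: {dtype: str}
      plot_id: {dtype: str}
      proportion: {dtype: float, doc: "fraction of plot area in [0,1]; sums to 1 per plot"}
      forest_type_group: {dtype: str}
      forest_type: {dtype: str}
      stand_age: {dtype: float, units: years}
      physiographic_class: {dtype: str}
      slope: {dtype: float, units: percent}
      aspect: {dtype: float, units: degrees, doc: "[0, 360)"}
      ownership: {dtype: str}
      disturbance: {dtype: str}
      at_plot_center: {dtype: bool, doc: exactly one true per plot}
      accessible_forest: {dtype: bool}
      artificial_regeneration: {dtype: bool}
      dwm_sampled: {dtype: bool}
      dwm_carbon: {dtype: float, units: Mg C / ha, doc: condition-level downed woody material C}
  trees:
    file: trees.csv
    columns:
      tree_id: {dtype: str}
      plot_id: {dtype: str}
      subplot: {dtype: int}
      species: {dtype: str}
      dbh: {dtype: float, units: cm, doc: ">= 12.7 for subplot trees"}
      status: {dtype: str, levels: [live, standing_dead, cut]}
      agc_kg: {dtype: float, units: kg C per stem, doc: "aboveground carbon, input column"}
      time: {dtype: int, levels: [1, 2]}
      expansion: {dtype: float, units: stems / ha, doc: per-ha expansion factor}
  seedlings:
    file: seedlings.csv
    columns:
      plot_id: {dtype: str}
      subplot: {dtype: int, doc: one microplot per subplot}
      species: {dtype: str}
      time: {dtype: int, levels: [1, 2]}
      count_class1: {dtype: int, doc: tally in shortest height class}
      count_class2: {dtype: int}
      count_class3: {dtype: int}
      count_class4: {dtype: int}
      count_class5: {dtype: int}
      count_class6: {dtype: int, doc: tally in tallest height class}
  saplings:
    file: saplings.csv
    columns:
      plot_id: {dtype: str}
      subplot: {dtype: int}
      species: {dtype: str}
      time: {dtype: int, levels: [1, 2]}
      present: {dtype: bool}
      newly_recruited: {dtype: bool, doc: "present at time 2, absent as sapling at time 1"}
height_classes:
  doc: "ordered index 1-6, smallest to tallest; class bounds are protocol metadata, configurable"
  labels: [lt15cm, 15-30cm, 30-60cm, 60-90cm, 90-150cm, gt150cm]
categorical_levels:
  physiographic_class: [hillslope, rolling_upland, flatwoods, floodplain, dry_slope, ridge, deep_sand, swamp]
  ownership: [private, national_forest, other_federal, state_local]
  disturbance: [none, insects, disease, fire, animals, weather, vegetation, human, unknown]
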