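# Catalogue of climate-mode index recipes.
#
# Boxes are [lat_min, lat_max, lon_min, lon_max] in degrees; longitudes
# may be given in 0..360 or -180..180 (normalized internally; boxes that
# cross the antimeridian are split automatically).
#
# annual_window options: annual (calendar mean), NDJFM / DJF / NDJ
# (window starts in the previous calendar year -> first ensemble year is
# undefined), JJA. pc-index recipes carry a sign_reference: the regression
# of the field on the PC over that box must have the given sign, fixing
# the arbitrary EOF orientation.
#
# Note the ENSO index is the (equatorial) Southern Oscillation Index, an
# SLP-based index: its positive phase is La Nina, the opposite sign
# convention to SST-based ENSO indices.

modes:
  ENSO:
    field: slp
    method: box-difference
    standardization: per-box
    boxes:
      - [-5, 5, 90, 140]     # Indo-Pacific
      - [-5, 5, -130, -80]   # Eastern Pacific
    annual_window: annual
    description: Equatorial Southern Oscillation Index (SOI); positive = La Nina.

  IOD:
    field: sst
    method: box-difference
    standardization: difference
    boxes:
      - [-10, 10, 50, 70]    # West Indian Ocean
      - [-10, 0, 90, 110]    # East Indian Ocean
    annual_window: annual
    description: Dipole Mode Index (DMI), west-minus-east Indian Ocean SST gradient.

  PDO:
    field: sst
    method: pc-index
    pc_rank: 1
    boxes:
      - [20, 70, 120, -100]  # North Pacific (crosses the antimeridian)
    annual_window: NDJFM
    sign_reference: {box: [30, 45, 160, -160], sign: -1}   # PDO+ = cool central N Pacific
    description: Pacific Decadal Oscillation, leading PC of North Pacific SST anomalies.

  TNA:
    field: sst
    method: box-anomaly
    boxes:
      - [5, 25, -55, -15]
    annual_window: annual
    description: Tropical North Atlantic SST anomaly.

  TSA:
    field: sst
    method: box-anomaly
    boxes:
      - [-20, 0, -30, 10]
    annual_window: annual
    description: Tropical South Atlantic SST anomaly.

  NAO:
    field: slp
    method: pc-index
    pc_rank: 1
    boxes:
      - [20, 80, -90, 40]    # North Atlantic sector
    annual_window: DJF
    sign_reference: {box: [60, 70, -45, -15], sign: -1}    # NAO+ = deep Icelandic low
    description: North Atlantic Oscillation, leading PC of North Atlantic SLP anomalies.

  EA:
    field: slp
    method: pc-index
    pc_rank: 2
    boxes:
      - [20, 80, -90, 40]
    annual_window: NDJ
    sign_reference: {box: [45, 60, -40, -10], sign: -1}    # EA+ = low west of Britain
    description: East Atlantic pattern, second PC of North Atlantic SLP anomalies.

  AO:
    field: slp
    method: pc-index
    pc_rank: 1
    boxes:
      - [20, 90, -180, 180]  # north of 20 N
    annual_window: DJF
    sign_reference: {box: [70, 90, -180, 180], sign: -1}   # AO+ = low Arctic SLP
    description: Arctic Oscillation, leading PC of SLP anomalies north of 20 N.

  PNA:
    field: slp
    method: pc-index
    pc_rank: 1
    djf_first: true          # DJF mean (starting the previous year) taken first
    boxes:
      - [20, 90, 120, -120]  # North Pacific / North America (crosses antimeridian)
    annual_window: annual    # the DJF-first PC is already one value per year
    sign_reference: {box: [45, 60, 160, -160], sign: -1}   # PNA+ = deep Aleutian low
    description: Pacific/North American pattern, leading PC of DJF-mean SLP anomalies.

  AMO:
    field: sst
    method: global-contrast
    boxes:
      - [0, 60, -75, -7.5]   # North Atlantic vs rest of global ocean
    annual_window: annual
    description: Atlantic Multidecadal Oscillation, Atlantic minus rest-of-ocean SST anomaly.

  SAM:
    field: slp
    method: pc-index
    pc_rank: 1
    boxes:
      - [-90, -20, -180, 180]  # south of 20 S
    annual_window: JJA
    sign_reference: {box: [-90, -65, -180, 180], sign: -1}  # SAM+ = low Antarctic SLP
    description: Southern Annular Mode, leading PC of SLP anomalies south of 20 S.
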