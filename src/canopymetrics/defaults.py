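"""Central numeric defaults for the measurement pipeline.

Every threshold used by the library and the CLI lives here so the two cannot
drift. Units are meters unless stated otherwise.
"""

# Outlier filter: mean distance to the K_NEIGHBORS nearest neighbours,
# points above OUTLIER_THRESHOLD are dropped (single pass).
K_NEIGHBORS = 20
OUTLIER_THRESHOLD = 0.30

# Tree location: circle fitted to the lowest LOCATION_SLICE_HEIGHT of the cloud.
LOCATION_SLICE_HEIGHT = 0.30

# DBH: circle fitted to the slice [base + DBH_SLICE_LO, base + DBH_SLICE_HI).
DBH_SLICE_LO = 1.27
DBH_SLICE_HI = 1.33

# Crown start: scan SLICE_HEIGHT slices upward from the DBH slice; the first
# slice whose fitted radius is >= CROWN_JUMP x the previous fitted radius
# marks the crown base. The scan is capped at CROWN_SCAN_CAP of tree height.
SLICE_HEIGHT = 0.10
CROWN_JUMP = 1.2
CROWN_SCAN_CAP = 0.60

# Crown radii: N_DIRECTIONS azimuths (5 degree steps), each measured inside a
# vertical slab of total width SLAB_WIDTH through the tree location.
N_DIRECTIONS = 72
SLAB_WIDTH = 0.10

# Height-banded crown radii: bands of BAND_HEIGHT up to MAX_BAND_HEIGHT above
# the tree base (15 bands).
BAND_HEIGHT = 2.0
MAX_BAND_HEIGHT = 30.0

# Minimum points for any structure-level circle fit (geometry itself needs 3;
# radius estimates on noisy slices are unstable below this).
MIN_CIRCLE_POINTS = 10

# QSM fit-quality check: points farther than this from every cylinder are
# flagged "not fitted".
UNFITTED_THRESHOLD = 0.05
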