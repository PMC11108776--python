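"""Shared constants.

Time-unit conversions are defined once here so every module uses the same
landmark definitions.
"""

# Average Gregorian month length in days.
DAYS_PER_MONTH = 30.4375

#: 24 weeks expressed in months (the clinical-benefit landmark).
WEEKS24_MONTHS = 24 * 7 / DAYS_PER_MONTH

#: One year expressed in months.
ONE_YEAR_MONTHS = 365.25 / DAYS_PER_MONTH

#: Default interaction radius in micrometres.
DEFAULT_RADIUS_UM = 50.0

#: MSIsensor score at or above which a sample is called MSI-H.
MSI_H_THRESHOLD = 3.5

#: The six-marker immunofluorescence panel (plus DAPI, which is implicit:
#: every row of a cell table is a nucleated cell).
PANEL_MARKERS = ("CD8", "PD1", "TOX", "FOXP3", "PDL1", "PAX8")
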