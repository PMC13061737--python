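"""Shared category and nutrient vocabularies.

The optimization decision space is the eight animal-source-food (ASF)
categories; plant foods form a fixed background during the search and are
only rescaled afterwards to close protein gaps.
"""

# The eight ASF decision categories. other_asf covers sheep/goat meat;
# aquatic_other covers non-fish seafood (shellfish, cephalopods).
ASF_CATEGORIES: tuple[str, ...] = (
    "beef",
    "pork",
    "poultry",
    "fish",
    "eggs",
    "dairy",
    "other_asf",
    "aquatic_other",
)

PLANT_CATEGORY = "plant_group"

CATEGORIES: tuple[str, ...] = ASF_CATEGORIES + (PLANT_CATEGORY,)

# Nutrient densities are stored per 100 g edible mass.
NUTRIENTS: tuple[str, ...] = (
    "protein",      # g
    "vitamin_a",    # ug RAE
    "vitamin_b12",  # ug
    "ala",          # g
    "epa",          # g
    "dha",          # g
    "energy",       # kcal
)

# Nutrients tracked for adequacy scoring and scenario prioritization.
TRACKED_NUTRIENTS: tuple[str, ...] = ("vitamin_a", "vitamin_b12", "epa", "dha")

# Nutrients that every scenario needs and that therefore are never masked
# by the missingness injector.
PROTECTED_NUTRIENTS: tuple[str, ...] = ("protein", "energy")

# WHO adult reference protein intake, g/person/day (~0.83 g/kg body weight).
WHO_PROTEIN_G = 60.0
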