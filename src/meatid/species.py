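"""Registry of the meat species handled by the default study panel.

Maps the trade names used on product labels and in mixture designs
("beef", "chevon", ...) to binomial species names and the genus that is
the reporting unit of the pipeline.
"""

from __future__ import annotations

# trade name -> (binomial species, genus)
MEAT_SPECIES: dict[str, tuple[str, str]] = {
    "pork": ("Sus scrofa", "Sus"),
    "beef": ("Bos taurus", "Bos"),
    "mutton": ("Ovis aries", "Ovis"),
    "chicken": ("Gallus gallus", "Gallus"),
    "turkey": ("Meleagris gallopavo", "Meleagris"),
    "chevon": ("Capra hircus", "Capra"),
    "ostrich": ("Struthio camelus", "Struthio"),
    "duck": ("Anas platyrhynchos", "Anas"),
    "kangaroo": ("Macropus giganteus", "Macropus"),
}

SPECIES_TO_COMMON = {binomial: common for common, (binomial, _) in MEAT_SPECIES.items()}


def resolve_species(name: str) -> str:
    """Return the binomial species name for a trade or binomial name.

    ``resolve_species("beef") == resolve_species("Bos taurus")``.
    Unrecognised names are returned unchanged (they may refer to species
    of a user-supplied panel) and are validated downstream against the
    panel taxonomy.
    """
    if name in MEAT_SPECIES:
        return MEAT_SPECIES[name][0]
    return name


def genus_of_common(name: str) -> str | None:
    """Genus for a trade name, or None if the name is not in the registry."""
    entry = MEAT_SPECIES.get(name)
    return entry[1] if entry else None
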