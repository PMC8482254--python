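{
  "description": "Reference list of 24 alcohol-related Twitter hashtags grouped by beverage category.",
  "note": "Beverage-category counts for this list circulate inconsistently (beer cited as both 14 and 19); the enumerated categorization below (14 beer, 5 wine, 3 liquor, 2 ambiguous) is followed here.",
  "categories": {
    "beer": [
      "craftbeer",
      "beer",
      "ncbeer",
      "brewery",
      "stout",
      "beeroclock",
      "beergeek",
      "beerporn",
      "beers",
      "instabeer",
      "beertime",
      "beerstagram",
      "beerlover",
      "beersnob"
    ],
    "wine": [
      "winetasting",
      "wine",
      "winelover",
      "wines",
      "redwine"
    ],
    "liquor": [
      "bourbon",
      "whiskey",
      "whisky"
    ],
    "ambiguous": [
      "drinklocal",
      "drunktwitter"
    ]
  }
}
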