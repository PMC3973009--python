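{
  "_comment": "Transcription of the two noun senses of 'gold' as returned by WordNet 2.1 (options -synsn -g): synset members, definition, example gloss, and direct hypernym with its definition. Used as a small sense-record lexicon for demonstrations and tests.",
  "morphology": {},
  "nouns": {
    "gold": [
      {
        "synonyms": ["gold"],
        "definition": "coins made of gold",
        "examples": [],
        "hypernyms": [
          {
            "synonyms": ["precious metal"],
            "definition": "less common and valuable metals often used to make coins or jewelry",
            "examples": []
          }
        ]
      },
      {
        "synonyms": ["amber", "gold"],
        "definition": "a deep yellow color",
        "examples": ["an amber light illuminated the room"],
        "hypernyms": [
          {
            "synonyms": ["yellow", "yellowness"],
            "definition": "yellow color or pigment",
            "examples": []
          }
        ]
      }
    ]
  }
}
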