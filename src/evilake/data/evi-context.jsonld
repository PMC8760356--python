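{
  "@context": {
    "@vocab": "https://w3id.org/EVI#",
    "evi": "https://w3id.org/EVI#",
    "prov": "http://www.w3.org/ns/prov#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "usedDataset": {"@id": "evi:usedDataset", "@type": "@id", "@container": "@list"},
    "usedSoftware": {"@id": "evi:usedSoftware", "@type": "@id", "@container": "@list"},
    "generatedBy": {"@id": "evi:generatedBy", "@type": "@id"},
    "parameters": {"@id": "evi:parameters", "@type": "@id"},
    "challenges": {"@id": "evi:challenges", "@type": "@id"},
    "evidenceGraph": {"@id": "evi:evidenceGraph", "@type": "@id"}
  },
  "@graph": [
    {"@id": "evi:Dataset", "rdfs:subClassOf": {"@id": "prov:Entity"}},
    {"@id": "evi:Software", "rdfs:subClassOf": {"@id": "prov:Entity"}},
    {"@id": "evi:Image", "rdfs:subClassOf": {"@id": "prov:Entity"}},
    {"@id": "evi:Computation", "rdfs:subClassOf": {"@id": "prov:Activity"}},
    {"@id": "evi:Challenge", "rdfs:subClassOf": {"@id": "prov:Entity"}}
  ]
}
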