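# External database registry: datatype<TAB>URL template ({id} is replaced
# by the identifier). Users may supply their own copy of this file to
# register additional databases.
ec-code	https://identifiers.org/ec-code/{id}
kegg.reaction	https://identifiers.org/kegg.reaction/{id}
kegg.compound	https://identifiers.org/kegg.compound/{id}
kegg.genes	https://identifiers.org/kegg.genes/{id}
kegg.pathway	https://identifiers.org/kegg.pathway/{id}
chebi	https://identifiers.org/chebi/{id}
obo.chebi	https://identifiers.org/chebi/{id}
uniprot	https://identifiers.org/uniprot/{id}
pubmed	https://identifiers.org/pubmed/{id}
doi	https://doi.org/{id}
taxonomy	https://identifiers.org/taxonomy/{id}
go	https://identifiers.org/go/{id}
sgd	https://identifiers.org/sgd/{id}
biocyc	https://identifiers.org/biocyc/{id}
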