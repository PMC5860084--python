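fibroblast
lymphocyte
macrophage
hepatocyte
keratinocyte
neutrophil
epithelial
endothelial
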