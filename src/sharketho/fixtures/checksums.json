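{
  "confusion_LR.csv": "68017796e62b47508d41118f9d600b1d6250638e70c22a0a3b4a7195a674a91b",
  "confusion_ANN.csv": "88a6042d76c409500c6e05df5bc6861a61ad629a87fd0b66b1c5186e201ff26b",
  "confusion_RFG.csv": "c49120a3184ef7d2109978822d11099bd2fe8402ae58301bce832c903586aff2",
  "confusion_RFE.csv": "fe9ad348099471c2ae97581a424dc5f85be58809b7fd41bd6ef603e152c7508f",
  "confusion_GB.csv": "881f52838d84f27d74414d2a5d364e0a8e14323754719f5fed5e965f272c27df",
  "confusion_VE.csv": "44e2496c01453b4cc084fbd0415e1ba9022be8c080379f4dd0bcdd1ab88d6e87"
}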