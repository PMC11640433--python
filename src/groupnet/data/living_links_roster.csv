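id,species,sex,group,age
Diego,capuchin,M,West,12.5
Lana,capuchin,F,West,19
Santiago,capuchin,F,West,13
Sylvania,capuchin,F,West,11.5
Toka,capuchin,M,West,10
Figo,capuchin,M,West,9
Pedra,capuchin,F,West,7
Mekoe,capuchin,M,West,7
Inti,capuchin,M,West,5
Rufo,capuchin,M,West,5
Ximo,capuchin,M,West,5
Torres,capuchin,M,West,4
Luna,capuchin,F,West,4
Alba,capuchin,F,West,3
Mr Fudge,capuchin,M,West,1.5
Bear,capuchin,M,West,1.5
Hazel,capuchin,F,West,1
Pixie,capuchin,F,West,1
Hugo,squirrel_monkey,M,West,4.5
Gerda,squirrel_monkey,F,West,15
Jasmin,squirrel_monkey,F,West,12
Toomi,squirrel_monkey,F,West,8
Dita,squirrel_monkey,F,West,5
Sancha,squirrel_monkey,F,West,5
Orla,squirrel_monkey,F,West,3
Gisele,squirrel_monkey,F,West,2.5
Loki,squirrel_monkey,F,West,1
Popeye,capuchin,M,East,13.5
Anita,capuchin,F,East,17
Junon,capuchin,F,East,14.5
Kato,capuchin,M,East,9.5
Manuel,capuchin,M,East,11
Penelope,capuchin,F,East,9
Carlos,capuchin,M,East,8.5
Chico,capuchin,M,East,6
Rosa,capuchin,F,East,5
Reuben,capuchin,M,East,4.5
Sol,capuchin,F,East,4.5
Flojo,capuchin,M,East,3.5
Lindo,capuchin,F,East,3.5
Willow,capuchin,F,East,2
Nena,capuchin,F,East,2
Gustavo,capuchin,M,East,1
Agnes,capuchin,F,East,1
Boa,squirrel_monkey,M,East,9
Tatu,squirrel_monkey,F,East,14
Roca,squirrel_monkey,F,East,12
Maya,squirrel_monkey,F,East,11
Elie,squirrel_monkey,F,East,9
Cali,squirrel_monkey,F,East,9
Pica,squirrel_monkey,F,East,7
Yendi,squirrel_monkey,F,East,6
Flora,squirrel_monkey,F,East,6
Sipi,squirrel_monkey,F,East,5
Lexi,squirrel_monkey,F,East,4
Dora,squirrel_monkey,F,East,4
Amarilla,squirrel_monkey,F,East,3
Pelusa,squirrel_monkey,F,East,3
Gabriela,squirrel_monkey,F,East,3
Valencia,squirrel_monkey,F,East,3
Ciara,squirrel_monkey,F,East,3
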