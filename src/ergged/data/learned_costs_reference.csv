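kind,label1,label2,value
node_sub,[0],[1],1.99
node_sub,[0],[2],2.02
node_sub,[0],[3],2.0
node_sub,[0],[4],1.99
node_sub,[0],[5],2.04
node_sub,[0],[6],2.05
node_sub,[0],[7],3.0
node_sub,[0],"[0,1]",1.06
node_sub,[0],"[0,2]",0.99
node_sub,[0],"[0,3]",1.0
node_sub,[0],"[1,2]",2.0
node_sub,[0],"[1,3]",2.0
node_sub,[0],"[2,3]",2.0
node_sub,[0],"[0,1,2]",0.97
node_sub,[1],[2],2.0
node_sub,[1],[3],2.0
node_sub,[1],[4],1.98
node_sub,[1],[5],1.99
node_sub,[1],[6],1.96
node_sub,[1],[7],3.0
node_sub,[1],"[0,1]",1.02
node_sub,[1],"[0,2]",1.99
node_sub,[1],"[0,3]",2.0
node_sub,[1],"[1,2]",1.02
node_sub,[1],"[1,3]",1.0
node_sub,[1],"[2,3]",2.0
node_sub,[1],"[0,1,2]",1.04
node_sub,[2],[3],2.0
node_sub,[2],[4],2.0
node_sub,[2],[5],2.0
node_sub,[2],[6],1.99
node_sub,[2],[7],3.0
node_sub,[2],"[0,1]",2.0
node_sub,[2],"[0,2]",0.99
node_sub,[2],"[0,3]",2.0
node_sub,[2],"[1,2]",1.0
node_sub,[2],"[1,3]",2.0
node_sub,[2],"[2,3]",1.0
node_sub,[2],"[0,1,2]",0.98
node_sub,[3],[4],2.0
node_sub,[3],[5],2.0
node_sub,[3],[6],2.05
node_sub,[3],[7],3.0
node_sub,[3],"[0,1]",1.99
node_sub,[3],"[0,2]",2.0
node_sub,[3],"[0,3]",1.0
node_sub,[3],"[1,2]",2.0
node_sub,[3],"[1,3]",1.0
node_sub,[3],"[2,3]",1.0
node_sub,[3],"[0,1,2]",2.0
node_sub,[4],[5],1.99
node_sub,[4],[6],2.01
node_sub,[4],[7],3.0
node_sub,[4],"[0,1]",2.01
node_sub,[4],"[0,2]",2.01
node_sub,[4],"[0,3]",2.0
node_sub,[4],"[1,2]",2.0
node_sub,[4],"[1,3]",2.0
node_sub,[4],"[2,3]",2.0
node_sub,[4],"[0,1,2]",2.0
node_sub,[5],[6],1.99
node_sub,[5],[7],3.0
node_sub,[5],"[0,1]",1.96
node_sub,[5],"[0,2]",1.96
node_sub,[5],"[0,3]",2.0
node_sub,[5],"[1,2]",2.0
node_sub,[5],"[1,3]",2.0
node_sub,[5],"[2,3]",2.0
node_sub,[5],"[0,1,2]",2.02
node_sub,[6],[7],3.0
node_sub,[6],"[0,1]",2.0
node_sub,[6],"[0,2]",2.01
node_sub,[6],"[0,3]",2.0
node_sub,[6],"[1,2]",2.0
node_sub,[6],"[1,3]",2.0
node_sub,[6],"[2,3]",2.0
node_sub,[6],"[0,1,2]",1.98
node_sub,[7],"[0,1]",3.0
node_sub,[7],"[0,2]",3.0
node_sub,[7],"[0,3]",3.0
node_sub,[7],"[1,2]",3.0
node_sub,[7],"[1,3]",3.0
node_sub,[7],"[2,3]",3.0
node_sub,[7],"[0,1,2]",3.0
node_sub,"[0,1]","[0,2]",2.02
node_sub,"[0,1]","[0,3]",2.0
node_sub,"[0,1]","[1,2]",2.0
node_sub,"[0,1]","[1,3]",2.0
node_sub,"[0,1]","[2,3]",2.0
node_sub,"[0,1]","[0,1,2]",2.01
node_sub,"[0,2]","[0,3]",2.0
node_sub,"[0,2]","[1,2]",2.0
node_sub,"[0,2]","[1,3]",2.0
node_sub,"[0,2]","[2,3]",2.0
node_sub,"[0,2]","[0,1,2]",2.0
node_sub,"[0,3]","[1,2]",2.0
node_sub,"[0,3]","[1,3]",2.0
node_sub,"[0,3]","[2,3]",2.0
node_sub,"[0,3]","[0,1,2]",2.0
node_sub,"[1,2]","[1,3]",2.0
node_sub,"[1,2]","[2,3]",2.0
node_sub,"[1,2]","[0,1,2]",2.0
node_sub,"[1,3]","[2,3]",2.0
node_sub,"[1,3]","[0,1,2]",2.0
node_sub,"[2,3]","[0,1,2]",2.0
node_indel,[0],,1.95
node_indel,[1],,1.98
node_indel,[2],,2.0
node_indel,[3],,2.0
node_indel,[4],,1.99
node_indel,[5],,1.89
node_indel,[6],,0.97
node_indel,[7],,1.0
node_indel,"[0,1]",,2.03
node_indel,"[0,2]",,2.02
node_indel,"[0,3]",,2.0
node_indel,"[1,2]",,1.99
node_indel,"[1,3]",,2.0
node_indel,"[2,3]",,2.0
node_indel,"[0,1,2]",,1.96
edge_sub,-,=,3.0
edge_sub,-,≡,3.0
edge_sub,=,≡,3.0
edge_indel,-,,0.0
edge_indel,=,,1.02
edge_indel,≡,,1.0
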